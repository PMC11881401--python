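"""3D localization of microhemorrhages on a synthetic two-channel phantom.

Generates a cleared-tissue-style phantom — tubular vessels with a
capillary-dominant diameter profile in the fluorescence channel, dark
hemosiderin deposit clusters in the transmission channel — then runs the
full analysis: vessel segmentation and centerline tracing, deposit
detection, and the five-nearest-vessel diameter statistic per deposit.
"""

import numpy as np

from cmhquant import PhantomSpec, RunConfig, localize_stacks
from cmhquant.synthetic import generate_deposit_channel, generate_vessel_phantom

spec = PhantomSpec(volume_shape=(110, 110, 110), n_vessels=40, n_lesions=5, seed=42)
fluor, truth = generate_vessel_phantom(spec)
trans, truth_deposits = generate_deposit_channel(spec, truth)

result = localize_stacks(fluor, trans, RunConfig())
summary = result["summary"]

print(f"vessels rendered:        {spec.n_vessels} (true diameters "
      f"{2 * truth.radii.min():.1f}-{2 * truth.radii.max():.1f} um)")
print(f"deposits detected:       {len(result['deposits'])} "
      f"({len(truth_deposits)} rendered; overlapping deposits merge)")
print(f"lesions (single-linkage at 100 um): {len(result['lesions'])} "
      "(nearby clusters chain together in a volume this small)")
print(f"nearest-vessel diameters pooled: n={summary['n']}, "
      f"range {summary['min_um']:.1f}-{summary['max_um']:.1f} um")
print(f"fraction below 10 um capillary cutoff: "
      f"{100 * summary['fraction_below_cutoff']:.1f}%")
print()
print("A fraction near 100% means the vessels surrounding the simulated")
print("bleeds are capillaries, matching the phantom's diameter profile.")
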