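#!/usr/bin/env python
"""Generate the synthetic study registries.

Writes three claim-style registries under results/data/: the reference
planted-module registry (3 modules x 15 diseases among 60, lift 4, 2,000
patients, 3 years, no drift), a drifting variant (10% of diseases change
module each year), and an independence control (lift 1).  Each registry is
a records CSV plus a ground-truth module-label CSV.
"""

from pathlib import Path

import comorbnet as cn
from comorbnet.synth import write_registry

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 0


def main() -> None:
    for name, spec in [
        ("planted", cn.reference_planted_spec(SEED, n_years=3, drift_rate=0.0)),
        ("drifting", cn.reference_planted_spec(SEED, n_years=3, drift_rate=0.1)),
        ("independent", cn.independence_spec(SEED)),
    ]:
        reg = cn.generate(spec)
        rec_path, truth_path = write_registry(reg, OUT / name)
        years = sorted(reg.truth)
        print(
            f"{name}: {len(reg.records)} records, {spec.n_diseases} diseases, "
            f"years {years[0]}-{years[-1]} -> {rec_path}"
        )


if __name__ == "__main__":
    main()
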