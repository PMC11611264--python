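#!/usr/bin/env python
"""Co-zonal pairing of dopaminergic and output-neuron driver lines.

Pairs PAM and MBON lines that share major anatomical staining (intensity
>= 3) in at least one mushroom-body zone, then regresses the MBON valence
effect size on the PAM effect size across pairs.  The staining tables
under data/ are synthetic stand-ins (see their filenames) with the same
shape as a real anatomical scoring table: line, delta_pi, one column per
zone (a1, b1, b2, bp1, bp2, g1-g5) holding a 0-5 staining intensity.
"""

from pathlib import Path

import pandas as pd

from optovalence import pair_cozonal

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 11


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    pam = pd.read_csv(ROOT / "data" / "pam_staining_synthetic.csv")
    mbon = pd.read_csv(ROOT / "data" / "mbon_staining_synthetic.csv")
    pairs, res = pair_cozonal(pam, mbon, staining_threshold=3, resamples=3000,
                              seed=SEED)
    pairs.to_csv(RESULTS / "cozonal_pairs.csv", index=False)
    print(f"{len(pairs)} co-zonal pair(s) at staining threshold 3")
    if res is not None:
        print(
            f"MBON dPI ~ {res.slope:+.2f} x PAM dPI {res.intercept:+.2f}; "
            f"R2 = {res.r_squared:.2f} [95CI {res.r2_ci_low:.2f}, "
            f"{res.r2_ci_high:.2f}], n = {res.n}"
        )
        pd.DataFrame([res.__dict__]).to_csv(
            RESULTS / "cozonal_regression.csv", index=False
        )
    print("wrote cozonal_pairs.csv, cozonal_regression.csv")


if __name__ == "__main__":
    main()
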