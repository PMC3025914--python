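#!/usr/bin/env python
"""Power of a prospective Cox test for a modest Lp(a)-like hazard ratio.

Rescales the literature hazard ratio of 1.22 per doubling of the trait
to the 25.4% per-allele change seen at the trait locus (HR 1.067), then
estimates by simulation the power of the per-allele Cox test in a
cohort of 3225 with exactly 389 incident events at allele frequency
0.19 — the design under which the association was examined and found
null.  Writes results/power/power.json.
"""

import json
from pathlib import Path

from admixlpa import PowerConfig, rescale_hr, simulate_power

OUT = Path(__file__).resolve().parent.parent / "results" / "power"
SEED = 6


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    hr = rescale_hr(1.22, 2.0, 1.254)
    print(f"HR 1.22 per doubling -> {hr:.3f} per one-allele (25.4%) change")

    cfg = PowerConfig(
        n=3225, n_events=389, allele_freq=0.19, hr_mean=round(hr, 3),
        alpha=0.05, n_iter=1000, seed=SEED,
    )
    res = simulate_power(cfg)
    print(f"power at alpha=0.05 over {cfg.n_iter} iterations: "
          f"{100 * res.power:.1f}% (MC se {100 * res.mc_se:.1f}%)")
    print("a per-allele HR of this size is essentially undetectable at 389 events")

    with open(OUT / "power.json", "w") as fh:
        json.dump({"hr_per_allele": round(hr, 3), "power": res.power,
                   "mc_se": res.mc_se, "n_iter": cfg.n_iter}, fh, indent=2)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
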