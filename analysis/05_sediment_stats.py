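#!/usr/bin/env python
"""Sediment-side statistics on the synthetic cores.

Three analyses: (1) Kruskal-Wallis comparisons of each element across surface
sediment in both pools and bottom sediment in the eelgrass pool; (2) a
Monte-Carlo Dwass-Steel-Critchlow-Fligner comparison of lead across
leaf-like, epiphyte-like and surface-sediment groups (the ~20-fold surface
enrichment pattern); (3) log-linear trends of every element on d13C fitted
per pool — positive and significant for metals in the eelgrass pool only.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from seagrass_metals import d13c_trend, kruskal_wallis, steel_dwass_mc
from seagrass_metals.sediment import ELEMENTS, significance_stars
from seagrass_metals.tables import read_table, write_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sed = read_table(ROOT / "synthetic" / "sediment.csv")
    surf = sed[sed["layer"] == "surface"]
    bottom_eel = sed[(sed["layer"] == "bottom") & (sed["pool"] == "eelgrass")]

    kw_rows = []
    for el in ELEMENTS:
        kw = kruskal_wallis(
            [
                surf[surf["pool"] == "eelgrass"][el].to_numpy(),
                surf[surf["pool"] == "reference"][el].to_numpy(),
                bottom_eel[el].to_numpy(),
            ]
        )
        kw_rows.append({"element": el, **kw, "stars": significance_stars(kw["p"])})
        print(
            f"KW {el:>10}: chi2={kw['chi2']:6.2f} df={kw['df']:.0f} "
            f"p={kw['p']:.4g} {significance_stars(kw['p'])}"
        )
    write_table(pd.DataFrame(kw_rows), ROOT / "sediment_kruskal.csv")

    # lead in leaf-like and epiphyte-like material vs surface sediment:
    # synthetic groups with the ~20-fold surface enrichment
    rng = np.random.default_rng(11)
    groups = {
        "leaf": rng.lognormal(np.log(1.0), 0.3, 10),
        "epiphytes": rng.lognormal(np.log(1.0), 0.3, 10),
        "surface_sediment": rng.lognormal(np.log(20.0), 0.3, 12),
    }
    res = steel_dwass_mc(groups, n_iter=10_000, seed=12)
    print("\nDSCF, lead across compartments:")
    for (a, b), stat, p in zip(res.pairs, res.statistics, res.p_values):
        print(f"  {a:>16} vs {b:<16} T={stat:5.2f} p={p:.4f} "
              f"{significance_stars(p)}")
    write_table(res.as_frame(), ROOT / "sediment_dscf_pb.csv")

    trend_rows = []
    print("\nlog-linear trends on d13C:")
    for pool in ("eelgrass", "reference"):
        for el in ELEMENTS:
            t = d13c_trend(sed, el, pool)
            trend_rows.append(
                {**dataclasses.asdict(t), "stars": significance_stars(t.p_slope)}
            )
            print(
                f"  {pool:>9} {el:>10}: slope {t.slope:+.3f} "
                f"p={t.p_slope:.4g} {significance_stars(t.p_slope)}"
            )
    out = write_table(pd.DataFrame(trend_rows), ROOT / "sediment_trends.csv")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
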