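"""Homogeneous-column MCPA fate under the two precipitation regimes.

Runs the pseudo-1D (HOM) scenario for continuous light rain and heavy rain
events on the reference column and tabulates depth-interval residual
concentrations, detectability durations, leachate at 30 cm, and DT50.
Finding: under heavy rain the pulse becomes detectable at 20-30 cm for
~21 days, leaching stays near 0.1% of the application, and DT50 is a few
days in both regimes (rain events slightly slow degradation).
"""

from pathlib import Path

import pandas as pd

from mcpafate import (
    Mesh,
    default_layers,
    depth_interval_series,
    detectability_duration,
    dt50,
    hre_clr_difference,
    leachate_metrics,
    simulate_scenario,
)
from mcpafate.precip import build_precip

OUT = Path(__file__).resolve().parents[1] / "results"
SPAN = 60.0


def main() -> None:
    layers = default_layers()
    mesh = Mesh.build(layers, width=0.3).column_mesh()
    runs = {}
    for label in ("CLR", "HRE"):
        runs[label] = simulate_scenario(
            mesh, layers, None, build_precip(label, SPAN), SPAN,
            label=f"HOM-{label}")
    OUT.mkdir(exist_ok=True)
    rows = []
    for label, res in runs.items():
        df = depth_interval_series(res, layers)
        df.to_csv(OUT / f"hom_{label.lower()}_intervals_mg_kg.csv")
        leachate_metrics(res).to_csv(OUT / f"hom_{label.lower()}_leachate.csv")
        for col in df.columns[:4]:
            dur = detectability_duration(df.index.to_numpy(),
                                         df[col].to_numpy() * 1e3)
            rows.append({"precip": label, "interval": col,
                         "detectable_days": round(dur, 1)})
        rows.append({"precip": label, "interval": "DT50",
                     "detectable_days": round(dt50(res), 2)})
        print(f"HOM-{label}: DT50 {dt50(res):.1f} d, leached "
              f"{100 * res.cum_leached_frac[-1]:.3f}% of applied")
    pd.DataFrame(rows).to_csv(OUT / "hom_detectability.csv", index=False)
    diff = hre_clr_difference(runs["CLR"], runs["HRE"])
    diff.to_csv(OUT / "hom_hre_minus_clr.csv")
    print("HRE-CLR normalized residual difference at day 8: "
          f"{diff['delta_CT_norm'].loc[8.0]:+.4f} (positive: rain slowed "
          "degradation in the homogeneous column)")
    print(f"wrote HOM fate tables to {OUT}")


if __name__ == "__main__":
    main()
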