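"""Scale-transition diagnosis of the macroscopic degradation rate.

Decomposes the topsoil-averaged rate of desk-scale runs into the mean-field
approximation, covariance and variance corrections and the higher-order
residual.  Finding: R_bar - MFA is increasingly negative from HOM through
HIGH to EXTR, the deficit is carried by the (negative) covariance between
substrate and degrader fields, and heavy-rain events transiently shrink
|COV| by re-homogenizing the substrate.
"""

from pathlib import Path

from mcpafate import Scenario, run_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
SPAN = 20.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    frames = {}
    for het, precip in (("HOM", "CLR"), ("HIGH", "CLR"), ("EXTR", "CLR"),
                        ("EXTR", "HRE")):
        scn = Scenario(het, precip, n_realizations=2, t_end_days=SPAN)
        d = run_scenario(scn).summary_decomposition()
        d.to_csv(OUT / f"decomposition_{het}_{precip}.csv", index=False)
        frames[(het, precip)] = d.set_index("time_days")

    day = 10.0
    print(f"R_bar - MFA at day {day:.0f} [umol C/m^3/d]:")
    for key, d in frames.items():
        print(f"  {key[0]}-{key[1]}: {d['R_minus_MFA'].loc[day]:+.3g} "
              f"(COV {d['COV'].loc[day]:+.3g}, VAR {d['VAR'].loc[day]:+.3g})")
    ehre = frames[("EXTR", "HRE")]
    print("EXTR-HRE |COV| before/at end of first event: "
          f"{abs(ehre['COV'].loc[2.0]):.3g} -> {abs(ehre['COV'].loc[3.0]):.3g}"
          " (rain homogenizes the substrate)")
    print(f"wrote decomposition tables to {OUT}")


if __name__ == "__main__":
    main()
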