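#!/usr/bin/env python
"""Charge-balance analysis of tau-RNA coacervation compositions.

Computes the Delta-tau187 net charge at pH 7, converts the droplet-forming
compositions into protein(+):RNA(-) charge ratios, and maps a molar-ratio
grid to locate the composition closest to 1:1 charge balance.  Writes
results/charge_balance.csv and prints the headline ratios.
"""

from pathlib import Path

import pandas as pd

from taurna import chargecalc, constructs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    dtau = constructs.delta_tau187()
    rna = chargecalc.RNASpec(name="RNA")
    trna = chargecalc.RNASpec(name="tRNA", chain_mass=25000.0)

    z = chargecalc.net_protein_charge(dtau, 7.0)
    print(f"Delta-tau187 net charge at pH 7.0: {z:+.2f} e "
          f"(molar mass {dtau.molar_mass:.0f} Da)")

    seven_to_one = chargecalc.mixture_at_mass_ratio(80.0, 7.0, dtau)
    report = chargecalc.charge_ratio(seven_to_one, dtau, rna)
    print(f"7:1 protein:RNA mass ratio -> charge ratio "
          f"{report.charge_ratio:.2f}:1")

    compositions = [
        ("80 uM + 222 ug/ml", chargecalc.MixtureComposition(80.0, 222.0)),
        ("161 uM + 444 ug/ml", chargecalc.MixtureComposition(161.0, 444.0)),
    ]
    for label, mix in compositions:
        r = chargecalc.charge_ratio(mix, dtau, rna).charge_ratio
        print(f"maximal-coverage composition {label}: charge ratio {r:.2f}:1")

    # molar-ratio grid with tRNA as a 25 kDa chain
    grid = []
    for ratio in (2, 4, 8, 16, 32):
        trna_uM = 10.0 / ratio
        grid.append(
            chargecalc.MixtureComposition(
                protein_uM=10.0, rna_ugml=trna_uM * trna.chain_mass / 1000.0
            )
        )
    table, optimum = chargecalc.charge_balance_map(grid, dtau, trna)
    best = 10.0 / (optimum.rna_ugml * 1000.0 / trna.chain_mass)
    print(f"molar-ratio grid {{2,4,8,16,32}}:1 -> optimum at {best:.0f}:1 "
          "(closest to 1:1 charge balance)")

    table.to_csv(OUT / "charge_balance.csv", index=False)
    print(f"wrote {OUT / 'charge_balance.csv'}")


if __name__ == "__main__":
    main()
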