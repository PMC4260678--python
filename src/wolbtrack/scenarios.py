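"""Canonical study scenarios: the experiment's design constants as simulator configs.

These encode the evolve-and-resequence design this package targets: a base
population carrying three cytoplasmic clades at ~55/25/20% relative
frequency among infected flies (clade VI most common, then V, then the
merged I_II_III group), an infected fraction of ~53%, an effective count of
75 transmitting lineages, and a 15-generation cold regime in which clade V
gains a selective advantage of about s = 0.18 (carrying it from ~25% to
~80%).
"""

from __future__ import annotations

from wolbtrack.clades import CladeSNPTable, DiagnosticSNP
from wolbtrack.simulate import SimulationParams

#: Clade labels in decreasing base-population frequency order.
CLADES = ["VI", "V", "I_II_III"]

#: Relative clade frequencies among infected flies in the base population.
BP_RELATIVE = {"VI": 0.55, "V": 0.25, "I_II_III": 0.20}

#: Fraction of flies infected in the base population.
BP_INFECTED = 0.53

#: Effective number of transmitting cytoplasmic lineages.
EFFECTIVE_SIZE = 75

#: Generations of the cold regime.
COLD_GENERATIONS = 15

#: Selection coefficient of clade V in the cold regime.
COLD_S = 0.18


def diagnostic_panel(n_per_clade: int = 20, contig: str = "wolb") -> CladeSNPTable:
    """Synthetic diagnostic-SNP panel: ``n_per_clade`` private SNPs per clade
    at distinct positions (stand-in for a real panel derived from haplotype
    alignments)."""
    snps = []
    pos = 1
    for clade in CLADES:
        for _ in range(n_per_clade):
            snps.append(DiagnosticSNP(contig, pos, "C", clade))
            pos += 7
    return CladeSNPTable(snps)


def cold_regime_params(
    seed: int,
    s: float = COLD_S,
    n_replicates: int = 3,
    include_uninfected: bool = False,
) -> SimulationParams:
    """Cold-regime simulation: N=75 lineages, 15 generations, clade V
    advantaged by ``s``.

    With ``include_uninfected`` the base population's ~47% uninfected
    fraction is included (clade frequencies scaled accordingly); otherwise
    all lineages are infected and clade frequencies are the relative ones
    Pool-Seq of the symbiont genome measures.
    """
    if include_uninfected:
        init = {c: f * BP_INFECTED for c, f in BP_RELATIVE.items()}
        init["uninfected"] = 1.0 - BP_INFECTED
    else:
        init = {**BP_RELATIVE, "uninfected": 0.0}
    return SimulationParams(
        n_lineages=EFFECTIVE_SIZE,
        generations=COLD_GENERATIONS,
        clades=CLADES,
        initial_frequencies=init,
        selection={"V": 1.0 + s},
        transmission_fidelity=1.0,
        ci_intensity=0.0,
        n_replicates=n_replicates,
        seed=seed,
    )


__all__ = [
    "CLADES",
    "BP_RELATIVE",
    "BP_INFECTED",
    "EFFECTIVE_SIZE",
    "COLD_GENERATIONS",
    "COLD_S",
    "diagnostic_panel",
    "cold_regime_params",
]
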