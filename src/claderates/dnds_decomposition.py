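"""Per-branch dN/dS decomposition of a fitted MG94 codon model.

A fitted branch of length t (expected substitutions per nucleotide site)
is split into its nonsynonymous and synonymous components by partitioning
the expected substitution flux of the branch's generator, then
normalizing each component by the corresponding fraction of *neutral*
flux (the same generator at omega = 1).  With that normalization the
branch's omega parameter and the reported dN/dS ratio coincide, and a
neutral branch has dN = dS = t exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from claderates.data_io import PhyloTree
from claderates.substitution_models import CodonModelSpec, build_mg94_Q

#: dS below this floor is treated as zero-but-printable: ratios are taken
#: against the floor and flagged as floor-inflated.
DS_FLOOR = 1e-9


class OmegaRatio(NamedTuple):
    value: float
    floor_inflated: bool

    def __float__(self) -> float:
        return self.value


@dataclass
class BranchRateTrees:
    """Total, dN and dS trees over one shared topology, plus per-branch omega."""

    total_tree: PhyloTree
    dN_tree: PhyloTree
    dS_tree: PhyloTree
    omega: dict[int, OmegaRatio] = field(default_factory=dict)


def _flux_fractions(spec: CodonModelSpec, omega: float) -> tuple[float, float]:
    """Synonymous and nonsynonymous shares of expected flux at the given omega."""
    Q = build_mg94_Q(spec, omega=omega)
    pi = spec.codon_pi()
    sp = spec.space
    flux = pi[sp.nb_i] * Q[sp.nb_i, sp.nb_j]
    syn = float(flux[sp.nb_syn].sum())
    nonsyn = float(flux[~sp.nb_syn].sum())
    return syn, nonsyn


def decompose_branch(spec: CodonModelSpec, branch, t: float) -> tuple[float, float]:
    """Split branch length t into (dN, dS), per nucleotide site.

    The branch generator (scaled to total flux 3 under its own omega)
    contributes expected synonymous flux E_S and nonsynonymous flux E_N
    over time t; these are divided by 3 f_S and 3 f_N, the neutral
    (omega = 1) flux fractions, giving substitutions per synonymous /
    nonsynonymous nucleotide site equivalent.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    syn_b, nonsyn_b = _flux_fractions(spec, spec.omega_for(branch))
    E_S = t * syn_b
    E_N = t * nonsyn_b
    syn_n, nonsyn_n = _flux_fractions(spec, 1.0)
    f_S = syn_n / 3.0
    f_N = nonsyn_n / 3.0
    if f_S <= 0:
        raise ValueError("degenerate frequencies: no synonymous flux under the neutral model")
    dS = E_S / (3.0 * f_S)
    dN = E_N / (3.0 * f_N) if f_N > 0 else 0.0
    return dN, dS


def omega_ratio(dN: float, dS: float, floor: float = DS_FLOOR) -> OmegaRatio:
    """dN/dS with the dS floor applied before division.

    When dS is at or below the floor the ratio is computed against the
    floor and flagged ``floor_inflated`` (a dN of 0 then gives ratio 0,
    still flagged).
    """
    if dN < 0 or dS < 0:
        raise ValueError("dN and dS must be non-negative")
    inflated = dS <= floor
    return OmegaRatio(dN / max(dS, floor), inflated)


def branch_rate_trees(spec: CodonModelSpec, tree: PhyloTree) -> BranchRateTrees:
    """Decompose every branch of a fitted tree into dN and dS trees.

    The returned trees share the input topology; branch lengths of the
    dN (dS) tree are the per-branch dN (dS) values, and ``omega`` maps
    branch ids to flagged dN/dS ratios.
    """
    total = tree.copy()
    dn_tree = tree.copy()
    ds_tree = tree.copy()
    omega: dict[int, OmegaRatio] = {}
    for node in tree.branches():
        dN, dS = decompose_branch(spec, node.index, node.length or 0.0)
        dn_tree.postorder[node.index].length = dN
        ds_tree.postorder[node.index].length = dS
        omega[node.index] = omega_ratio(dN, dS)
    return BranchRateTrees(total, dn_tree, ds_tree, omega)


def branch_table(trees: BranchRateTrees) -> "pd.DataFrame":
    """Per-branch (t, dN, dS, omega) table for the three annotation trees."""
    import pandas as pd

    rows = []
    for node in trees.total_tree.branches():
        idx = node.index
        om = trees.omega[idx]
        rows.append({
            "branch": idx,
            "label": node.label if node.is_tip else "",
            "t": node.length,
            "dN": trees.dN_tree.postorder[idx].length,
            "dS": trees.dS_tree.postorder[idx].length,
            "omega": om.value,
            "floor_inflated": om.floor_inflated,
        })
    return pd.DataFrame(rows)
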