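"""Synthetic study generator: trees, alignments, richness, and the packaged fixture.

The generator emulates the data structure a sister-pairs rate study
assumes: independent cherries (sister-lineage pairs) hung off a
backbone, both tips of a cherry at the same time depth, with per-lineage
rate multipliers scaling the expected substitutions accumulated since
the split.  Species richness per lineage is drawn from a constant-rate
birth-death process conditioned on survival, whose speciation rate can
be coupled (kappa > 0) or not (kappa = 0) to the lineage's rate
multiplier — so both the null calibration and the power of the
signed-rank contrast are exercisable without any real data.

Default conditions mirror the study design being emulated: 20 sister
pairs, chloroplast-like branch lengths of order 0.01 substitutions/site,
~2-fold lineage rate spread, and birth-death richness with mean around
20 extant species per lineage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from claderates.data_io import Alignment, CodonAlignment, PhyloTree, TreeNode
from claderates.likelihood_engine import ReversibleMarkov
from claderates.sister_pairs import SisterPairDef
from claderates.substitution_models import (
    CodonFreqs3x4,
    CodonModelSpec,
    ExchangeabilityPartition,
    NucModelSpec,
    build_mg94_Q,
    build_nuc_Q,
    rate_categories,
)

TABLE1_SHA256 = "74cd4861d1358c5496c8496a4c22767187983337812a2c8b8c221dfa35fe2167"


@dataclass
class SimConfig:
    """Conditions for one synthetic study."""

    seed: int
    n_pairs: int = 20
    pair_depth: float = 0.01        # expected subs/site from split to tip at multiplier 1
    backbone_length: float = 0.005  # internal backbone branch lengths
    stem_length: float = 0.005      # cherry stem branch lengths
    n_codons: int = 500
    multiplier_spread: float = 2.0  # ~spread of lineage rate multipliers (lognormal)
    rate_multipliers: dict[str, float] | None = None
    kappa: float = 0.0              # coupling of log speciation rate to log multiplier
    birth_rate: float = 3.0         # lambda0, per unit crown age
    death_rate: float = 0.0         # mu
    crown_age: float = 1.0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")


def lineage_ids(cfg: SimConfig) -> list[str]:
    out = []
    for k in range(1, cfg.n_pairs + 1):
        out += [f"A{k}", f"B{k}"]
    return out


def draw_multipliers(cfg: SimConfig, rng: np.random.Generator) -> dict[str, float]:
    """Lognormal lineage rate multipliers with roughly cfg.multiplier_spread range."""
    if cfg.rate_multipliers is not None:
        return dict(cfg.rate_multipliers)
    sigma = np.log(cfg.multiplier_spread) / 2.0
    return {
        lid: float(np.exp(rng.normal(0.0, sigma))) for lid in lineage_ids(cfg)
    }


def simulate_pair_tree(cfg: SimConfig) -> tuple[PhyloTree, list[SisterPairDef], dict[str, float]]:
    """Independent equal-depth cherries on a comb backbone.

    Tips ``A<k>``/``B<k>`` form pair k; each tip branch is
    ``pair_depth * multiplier(lineage)``, so with all multipliers 1 every
    within-pair contrast is zero.  Returns (tree, pair definitions with
    placeholder richness 1, multipliers used).  Fixed seed gives
    byte-identical Newick output.
    """
    rng = np.random.default_rng(cfg.seed)
    mult = draw_multipliers(cfg, rng)

    def cherry(k: int) -> TreeNode:
        stem = TreeNode(length=cfg.stem_length)
        for lid in (f"A{k}", f"B{k}"):
            tip = TreeNode(lid, cfg.pair_depth * mult[lid])
            tip.parent = stem
            stem.children.append(tip)
        return stem

    # comb: ((...((cherry_1, OUT), cherry_2), ...), cherry_n)
    node = cherry(1)
    out = TreeNode("OUT", cfg.pair_depth)
    root = TreeNode()
    for k in range(2, cfg.n_pairs + 1):
        root = TreeNode()
        for child in (node, cherry(k)):
            child.parent = root
            root.children.append(child)
        node = root
        node.length = cfg.backbone_length
    root = TreeNode()
    for child in (node, out):
        child.parent = root
        root.children.append(child)
    node.length = cfg.backbone_length
    tree = PhyloTree(root)
    pairs = [
        SisterPairDef(
            pair_id=str(k),
            rich_tips=frozenset({f"A{k}"}), poor_tips=frozenset({f"B{k}"}),
            richness_rich=1, richness_poor=1,
        )
        for k in range(1, cfg.n_pairs + 1)
    ]
    return tree, pairs, mult


def default_codon_model(omega: float = 0.3, pattern: str = "012313") -> CodonModelSpec:
    """A realistic chloroplast-like MG94 spec for simulation defaults."""
    part = ExchangeabilityPartition(pattern)
    theta = np.linspace(1.0, 2.0, part.classes)
    nuc = NucModelSpec(partition=part, theta=theta, pi=np.array([0.31, 0.18, 0.20, 0.31]))
    freqs = CodonFreqs3x4(np.array([
        [0.30, 0.18, 0.25, 0.27],
        [0.30, 0.22, 0.17, 0.31],
        [0.29, 0.16, 0.17, 0.38],
    ]))
    return CodonModelSpec(nuc=nuc, freqs=freqs, omega_shared=omega)


def default_nuc_model(pattern: str = "010010") -> NucModelSpec:
    part = ExchangeabilityPartition(pattern)
    theta = np.ones(part.classes)
    if part.classes > 1:
        theta[0] = 0.5  # transversions slower than transitions
    return NucModelSpec(partition=part, theta=theta,
                        pi=np.array([0.30, 0.19, 0.21, 0.30]))


def simulate_alignment(
    tree: PhyloTree, model, n_sites: int, seed: int
) -> Alignment | CodonAlignment:
    """Evolve sequences down the tree under the model's own generator.

    Root states are drawn from the stationary distribution; each branch
    applies its transition matrix (per-branch omega respected for codon
    models; discrete-gamma site rates drawn per site).  The codon state
    space contains only sense codons, so stop codons are unreachable and
    nothing is rejected.
    """
    rng = np.random.default_rng(seed)
    is_codon = isinstance(model, CodonModelSpec)
    if is_codon:
        pi = model.codon_pi()
        rates, weights = rate_categories(model.nuc)

        def branch_markov(node):
            return ReversibleMarkov(build_mg94_Q(model, branch=node.index), pi)
    else:
        Q, rates, weights = build_nuc_Q(model)
        pi = model.pi
        shared = ReversibleMarkov(Q, pi)

        def branch_markov(node):
            return shared

    n_states = len(pi)
    cat = rng.choice(len(rates), size=n_sites, p=weights)
    site_rate = rates[cat]
    states: dict[int, np.ndarray] = {
        tree.root.index: rng.choice(n_states, size=n_sites, p=pi)
    }
    unique_rates = np.unique(site_rate)
    for node in reversed(tree.postorder):  # preorder
        if node.parent is None:
            continue
        mk = branch_markov(node)
        parent = states[node.parent.index]
        child = np.empty(n_sites, dtype=int)
        t = node.length or 0.0
        for r in unique_rates:
            mask = site_rate == r
            P = mk.P(t * r)
            rows = P[parent[mask]]
            rows = rows / rows.sum(axis=1, keepdims=True)
            u = rng.random(mask.sum())
            child[mask] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[node.index] = child

    labels = tree.tip_labels()
    if is_codon:
        mat = np.stack([states[tree.tip_index[lb]] for lb in labels])
        return CodonAlignment(labels, mat, genetic_code=model.genetic_code)
    symbols = np.array(list("ACGT"))
    mat = np.stack([symbols[states[tree.tip_index[lb]]] for lb in labels])
    return Alignment(labels, mat)


def survival_conditioned_richness(
    lam: float, mu: float, T: float, rng: np.random.Generator
) -> int:
    """Extant species count of a birth-death clade conditioned on survival.

    For a constant-rate process started from one lineage T units ago, the
    surviving-clade size is geometric: P(N = n) = (1 - eta) eta^(n-1),
    with eta = lambda (1 - e^(-rT)) / (lambda - mu e^(-rT)), r = lambda - mu.
    """
    if not lam > mu >= 0:
        raise ValueError("need lambda > mu >= 0")
    r = lam - mu
    e = np.exp(-r * T)
    eta = lam * (1.0 - e) / (lam - mu * e)
    # very fast diversification drives eta -> 1; clamp the geometric success
    # probability away from 0 so sampling stays well-defined
    p = max(1.0 - eta, 1e-12)
    return int(rng.geometric(p))


def simulate_richness(
    cfg: SimConfig, multipliers: dict[str, float], seed: int | None = None
) -> dict[str, int]:
    """Per-lineage species counts, speciation rate coupled to the rate multiplier.

    log lambda = log lambda0 + kappa * log(multiplier); extinction is held
    fixed, so kappa acts through net diversification.  kappa = 0 makes
    richness independent of the substitution-rate multipliers.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    out = {}
    for lid in sorted(multipliers):
        lam = float(np.exp(np.log(cfg.birth_rate) + cfg.kappa * np.log(multipliers[lid])))
        out[lid] = survival_conditioned_richness(lam, cfg.death_rate, cfg.crown_age, rng)
    return out


def simulate_contrast_table(cfg: SimConfig) -> pd.DataFrame:
    """Table-level study draw: true branch-length contrasts plus richness.

    Skips sequence simulation entirely: each lineage's value is its true
    tip branch length (depth x multiplier).  Suitable for type-I-error
    and power calibration of the signed-rank test.
    """
    rng = np.random.default_rng(cfg.seed)
    mult = draw_multipliers(cfg, rng)
    richness = simulate_richness(cfg, mult, seed=int(rng.integers(2 ** 31)))
    rows = []
    for k in range(1, cfg.n_pairs + 1):
        a, b = f"A{k}", f"B{k}"
        va, vb = cfg.pair_depth * mult[a], cfg.pair_depth * mult[b]
        if richness[a] >= richness[b]:
            rich, poor, vr, vp = a, b, va, vb
        else:
            rich, poor, vr, vp = b, a, vb, va
        rows.append({
            "pair_id": str(k),
            "richness_rich": richness[rich], "richness_poor": richness[poor],
            "total_rich": vr, "total_poor": vp,
        })
    return pd.DataFrame(rows)


def make_table1_fixture(verify: bool = True) -> pd.DataFrame:
    """The packaged 20-pair fixture table (richness, total, dN, dS, omega).

    Values are transcribed from the published per-lineage estimates, not
    recomputed; a checksum guards the transcription.
    """
    ref = resources.files("claderates.data").joinpath("table1.tsv")
    raw = ref.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE1_SHA256:
            raise RuntimeError(
                f"table1.tsv checksum mismatch: {digest} != {TABLE1_SHA256}"
            )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")
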