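"""Nucleotide and codon substitution models.

Two model families are built here:

* GTR-nested nucleotide models.  The six exchangeability slots
  (AC, AG, AT, CG, CT, GT) may be tied into equality classes in any of
  Bell(6) = 203 ways; each tying is an :class:`ExchangeabilityPartition`
  encoded as a restricted-growth string (``"012345"`` is full GTR,
  ``"000000"`` is Jukes-Cantor-like).  Optional discrete-gamma rate
  heterogeneity and a proportion of invariant sites are supported.

* The MG94 codon model crossed with any of those 203 exchangeability
  patterns, with 3x4 codon frequencies (one nucleotide frequency vector
  per codon position, stop codons removed and renormalized) and a
  per-branch or shared nonsynonymous/synonymous rate ratio omega.

All rate matrices are proper reversible generators.  Scaling convention:
branch lengths are expected substitutions per *nucleotide* site for both
families, so the nucleotide generator has unit flux and the codon
generator has flux 3 (three nucleotide sites per codon).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: ordered exchangeability slots (unordered base pairs)
SLOTS = ("AC", "AG", "AT", "CG", "CT", "GT")
_SLOT_INDEX = {}
for _k, _s in enumerate(SLOTS):
    _SLOT_INDEX[(BASE_INDEX[_s[0]], BASE_INDEX[_s[1]])] = _k
    _SLOT_INDEX[(BASE_INDEX[_s[1]], BASE_INDEX[_s[0]])] = _k

#: slot whose class is fixed to theta = 1 for identifiability (AG)
REFERENCE_SLOT = 1


def _normalize_pattern(digits: str) -> str:
    """Map an arbitrary 6-digit tying string to restricted-growth form."""
    relabel: dict[str, int] = {}
    out = []
    for d in digits:
        if d not in relabel:
            relabel[d] = len(relabel)
        out.append(str(relabel[d]))
    return "".join(out)


@dataclass(frozen=True)
class ExchangeabilityPartition:
    """A tying of the six GTR exchangeability slots into equality classes.

    ``pattern`` is a restricted-growth string: digit i gives the class of
    slot i, and classes are numbered by first occurrence (so the first
    digit is always 0).
    """

    pattern: str

    def __post_init__(self):
        if len(self.pattern) != len(SLOTS) or not self.pattern.isdigit():
            raise ValueError(f"pattern must be {len(SLOTS)} digits, got {self.pattern!r}")
        if self.pattern != _normalize_pattern(self.pattern):
            raise ValueError(
                f"pattern {self.pattern!r} is not in restricted-growth form; "
                "use parse_model_label to normalize"
            )

    @property
    def classes(self) -> int:
        return len(set(self.pattern))

    @property
    def slot_classes(self) -> tuple[int, ...]:
        return tuple(int(d) for d in self.pattern)

    def class_of_pair(self, a: int, b: int) -> int:
        """Class index for the unordered base pair (a, b), base indices in ACGT order."""
        return int(self.pattern[_SLOT_INDEX[(a, b)]])

    def constraint_sets(self) -> list[tuple[str, ...]]:
        """Slots grouped by class, e.g. [('AC',), ('AG','CT'), ...]."""
        groups: dict[str, list[str]] = {}
        for slot, d in zip(SLOTS, self.pattern):
            groups.setdefault(d, []).append(slot)
        return [tuple(groups[d]) for d in sorted(groups)]

    def label(self, prefix: str = "MG94_3x4_") -> str:
        return prefix + self.pattern


def _restricted_growth_strings(n: int) -> list[str]:
    patterns: list[str] = []

    def grow(prefix: str, max_used: int):
        if len(prefix) == n:
            patterns.append(prefix)
            return
        for d in range(max_used + 2):
            grow(prefix + str(d), max(max_used, d))

    grow("0", 0)
    return patterns


def enumerate_exchangeability_partitions() -> list[ExchangeabilityPartition]:
    """All 203 tyings of the six GTR exchangeability slots.

    203 is the Bell number of 6.  Order is lexicographic on the
    restricted-growth string, which is also the natural generation order.
    """
    return [ExchangeabilityPartition(p) for p in _restricted_growth_strings(len(SLOTS))]


def count_partitions(n_slots: int) -> int:
    """Number of distinct tyings of ``n_slots`` labelled slots (Bell number)."""
    if n_slots < 1:
        raise ValueError("n_slots must be positive")
    return len(_restricted_growth_strings(n_slots))


def parse_model_label(label: str) -> ExchangeabilityPartition:
    """Parse a model label whose suffix is a 6-digit tying string.

    Accepts bare digit strings (``"012313"``) or prefixed labels
    (``"MG94_3x4_012313"``).  Non-canonical digit strings are normalized
    to restricted-growth form, not rejected.
    """
    digits = label.rsplit("_", 1)[-1] if "_" in label else label
    if len(digits) != len(SLOTS) or not digits.isdigit():
        raise ValueError(f"model label must end in {len(SLOTS)} digits: {label!r}")
    return ExchangeabilityPartition(_normalize_pattern(digits))


# ---------------------------------------------------------------------------
# nucleotide models


@dataclass
class NucModelSpec:
    """A GTR-nested nucleotide model, optionally + gamma + invariant sites.

    ``theta`` has one entry per exchangeability class; the class containing
    the AG slot is fixed to 1 for identifiability.  ``pi`` are stationary
    base frequencies in ACGT order (typically empirical).
    """

    partition: ExchangeabilityPartition
    theta: np.ndarray
    pi: np.ndarray
    gamma_shape: float | None = None
    p_inv: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.theta.shape != (self.partition.classes,):
            raise ValueError("theta must have one entry per exchangeability class")
        if np.any(self.theta <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.pi.shape != (4,) or np.any(self.pi < 0) or abs(self.pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be 4 non-negative frequencies summing to 1")
        if self.p_inv is not None and not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")

    @property
    def reference_class(self) -> int:
        return int(self.partition.pattern[REFERENCE_SLOT])

    @property
    def free_theta_indices(self) -> list[int]:
        return [i for i in range(self.partition.classes) if i != self.reference_class]

    @property
    def n_free_params(self) -> int:
        """Free model parameters excluding branch lengths (frequencies counted)."""
        k = (self.partition.classes - 1) + 3
        if self.gamma_shape is not None:
            k += 1
        if self.p_inv is not None:
            k += 1
        return k

    def copy(self) -> "NucModelSpec":
        return replace(self, theta=self.theta.copy(), pi=self.pi.copy())


def gamma_category_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Discrete-gamma category rates: mean of each equal-probability quantile bin.

    The underlying distribution is Gamma(alpha, alpha) (mean 1); the k
    returned rates therefore average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), alpha, scale=1.0 / alpha)
    # E[X; a < X < b] for Gamma(alpha, alpha) is I(alpha+1, b*alpha) - I(alpha+1, a*alpha)
    cum = np.empty(k + 1)
    cum[0], cum[-1] = 0.0, 1.0
    cum[1:-1] = gammainc(alpha + 1.0, edges[1:-1] * alpha)
    return k * np.diff(cum)


def rate_categories(spec: NucModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Site-rate mixture (rates, weights) for a model spec.

    Gamma categories have mean 1 over the non-invariant fraction; an
    invariant class (rate 0, weight p_inv) is prepended when requested.
    """
    if spec.gamma_shape is not None:
        rates = gamma_category_rates(spec.gamma_shape, spec.n_rate_categories)
    else:
        rates = np.array([1.0])
    weights = np.full(rates.shape, 1.0 / len(rates))
    if spec.p_inv:
        rates = np.concatenate([[0.0], rates])
        weights = np.concatenate([[spec.p_inv], weights * (1.0 - spec.p_inv)])
    return rates, weights


def build_nuc_Q(spec: NucModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the scaled 4x4 generator plus its site-rate mixture.

    Returns ``(Q, rates, weights)``.  Off-diagonals are
    ``theta_class(a,b) * pi_b``; the matrix is rescaled so the expected
    flux ``-sum_a pi_a Q_aa`` is exactly 1 (branch lengths in expected
    substitutions per site).
    """
    Q = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            if a != b:
                Q[a, b] = spec.theta[spec.partition.class_of_pair(a, b)] * spec.pi[b]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    flux = -(spec.pi * np.diag(Q)).sum()
    if flux <= 0:
        raise ValueError("degenerate frequencies: zero expected flux")
    Q /= flux
    rates, weights = rate_categories(spec)
    return Q, rates, weights


# ---------------------------------------------------------------------------
# codon state space and MG94


@lru_cache(maxsize=None)
def _codon_space(code_id: int) -> "CodonStateSpace":
    return CodonStateSpace(code_id)


class CodonStateSpace:
    """Sense codons of a genetic code, with precomputed single-step moves.

    Codons are ordered lexicographically over ACGT.  ``neighbors`` holds,
    for every ordered pair of sense codons differing at exactly one
    position, the arrays (i, j, position, from-base, to-base, synonymous).
    """

    def __init__(self, code_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[code_id]
        self.code_id = code_id
        self.stop_codons = frozenset(table.stop_codons)
        self.codons = tuple(
            "".join(c) for c in itertools.product(BASES, repeat=3)
            if "".join(c) not in self.stop_codons
        )
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.amino_acids = tuple(table.forward_table[c] for c in self.codons)
        self.n_states = len(self.codons)

        I, J, P, A, B, syn = [], [], [], [], [], []
        for i, ci in enumerate(self.codons):
            for p in range(3):
                for b in BASES:
                    if b == ci[p]:
                        continue
                    cj = ci[:p] + b + ci[p + 1:]
                    j = self.index.get(cj)
                    if j is None:
                        continue
                    I.append(i)
                    J.append(j)
                    P.append(p)
                    A.append(BASE_INDEX[ci[p]])
                    B.append(BASE_INDEX[b])
                    syn.append(self.amino_acids[i] == self.amino_acids[j])
        self.nb_i = np.array(I)
        self.nb_j = np.array(J)
        self.nb_pos = np.array(P)
        self.nb_from = np.array(A)
        self.nb_to = np.array(B)
        self.nb_syn = np.array(syn, dtype=bool)

    def translate(self, codon: str) -> str | None:
        """Amino acid for a sense codon, '*' for stop, None if ambiguous."""
        if codon in self.stop_codons:
            return "*"
        i = self.index.get(codon)
        return None if i is None else self.amino_acids[i]

    @staticmethod
    def get(code_id: int = 1) -> "CodonStateSpace":
        return _codon_space(code_id)


@dataclass
class CodonFreqs3x4:
    """Position-specific nucleotide frequencies, 3 rows (codon positions) x 4 bases."""

    position_freqs: np.ndarray

    def __post_init__(self):
        self.position_freqs = np.asarray(self.position_freqs, dtype=float)
        if self.position_freqs.shape != (3, 4):
            raise ValueError("position_freqs must be 3x4")
        if np.any(self.position_freqs < 0):
            raise ValueError("frequencies must be non-negative")
        rows = self.position_freqs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-8):
            raise ValueError("each position's frequencies must sum to 1")

    def codon_pi(self, space: CodonStateSpace) -> np.ndarray:
        """Stationary codon frequencies: products over positions, stops removed, renormalized."""
        f = self.position_freqs
        pi = np.array(
            [f[0, BASE_INDEX[c[0]]] * f[1, BASE_INDEX[c[1]]] * f[2, BASE_INDEX[c[2]]]
             for c in space.codons]
        )
        total = pi.sum()
        if total <= 0:
            raise ValueError("degenerate position frequencies: all sense codons have zero mass")
        return pi / total

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.0) -> "CodonFreqs3x4":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum(axis=1, keepdims=True))

    @classmethod
    def uniform(cls) -> "CodonFreqs3x4":
        return cls(np.full((3, 4), 0.25))


@dataclass
class CodonModelSpec:
    """MG94 x (3x4 frequencies) x (GTR-nested exchangeabilities) with per-branch omega.

    ``nuc`` supplies the exchangeability tying and theta values (its ``pi``
    is unused by the codon generator); site-rate heterogeneity, if any, is
    taken from ``nuc`` as well.  ``omega_map`` maps branch ids to omega;
    ``omega_shared`` is used for any branch not in the map.
    """

    nuc: NucModelSpec
    freqs: CodonFreqs3x4
    omega_map: dict = field(default_factory=dict)
    omega_shared: float = 1.0
    genetic_code: int = 1

    @property
    def space(self) -> CodonStateSpace:
        return CodonStateSpace.get(self.genetic_code)

    def omega_for(self, branch) -> float:
        if branch in self.omega_map:
            return self.omega_map[branch]
        if self.omega_map and branch is not None:
            raise KeyError(f"branch {branch!r} has no omega assigned")
        return self.omega_shared

    def codon_pi(self) -> np.ndarray:
        return self.freqs.codon_pi(self.space)

    def copy(self) -> "CodonModelSpec":
        return CodonModelSpec(
            nuc=self.nuc.copy(),
            freqs=CodonFreqs3x4(self.freqs.position_freqs.copy()),
            omega_map=dict(self.omega_map),
            omega_shared=self.omega_shared,
            genetic_code=self.genetic_code,
        )


def _mg94_raw_Q(spec: CodonModelSpec, omega: float) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled MG94 generator and the codon stationary distribution."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    sp = spec.space
    f = spec.freqs.position_freqs
    theta = spec.nuc.theta
    part = spec.nuc.partition
    slot_class = np.array(
        [[part.class_of_pair(a, b) if a != b else 0 for b in range(4)] for a in range(4)]
    )
    rates = theta[slot_class[sp.nb_from, sp.nb_to]] * f[sp.nb_pos, sp.nb_to]
    rates = np.where(sp.nb_syn, rates, rates * omega)
    Q = np.zeros((sp.n_states, sp.n_states))
    Q[sp.nb_i, sp.nb_j] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, spec.codon_pi()


def build_mg94_Q(spec: CodonModelSpec, branch=None, omega: float | None = None) -> np.ndarray:
    """61x61 MG94 generator for one branch, flux-scaled.

    Off-diagonal entries exist only for single-nucleotide codon changes:
    ``theta_class(a,b) * f[pos][b]``, multiplied by the branch's omega for
    nonsynonymous changes.  The matrix is rescaled so the expected number
    of codon substitutions per unit time is 3 (one per nucleotide site),
    under this branch's own omega.
    """
    if omega is None:
        if branch is not None and branch not in spec.omega_map and spec.omega_map:
            raise KeyError(f"branch {branch!r} has no omega assigned")
        omega = spec.omega_for(branch)
    Q, pi = _mg94_raw_Q(spec, omega)
    flux = -(pi * np.diag(Q)).sum()
    if flux <= 0:
        raise ValueError("degenerate codon frequencies: zero expected flux")
    return Q * (3.0 / flux)


def empirical_base_freqs(counts: np.ndarray) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        return np.full(4, 0.25)
    return c / c.sum()
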