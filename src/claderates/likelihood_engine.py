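"""Phylogenetic likelihoods on a fixed topology, and the fits built on them.

The core is Felsenstein's pruning algorithm over compressed site
patterns, with per-pattern rescaling to avoid underflow and transition
probabilities from the eigendecomposition of the pi-symmetrized
generator (time-reversible models have a real spectrum).  On top of it:

* coordinate-wise maximum-likelihood branch-length optimization with
  optional updates of exchangeabilities, gamma shape, invariant fraction
  and (for codon models) shared or per-branch omega;
* BIC selection of nucleotide models per alignment partition;
* AIC selection among the 203 MG94 exchangeability-tying variants;
* the constant-rates (strict clock) versus free-rates likelihood-ratio
  test used to demonstrate among-lineage rate variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2

from claderates.data_io import (
    BRANCH_LENGTH_FLOOR,
    IUPAC,
    MISSING_CODON,
    Alignment,
    CodonAlignment,
    PhyloTree,
    check_labels_match,
)
from claderates.substitution_models import (
    CodonFreqs3x4,
    CodonModelSpec,
    ExchangeabilityPartition,
    NucModelSpec,
    build_mg94_Q,
    build_nuc_Q,
    rate_categories,
)

logger = logging.getLogger(__name__)

DEFAULT_LOGL_TOL = 1e-8
DEFAULT_BL_TOL = 1e-7
DEFAULT_MAX_SWEEPS = 200
MAX_BRANCH_LENGTH = 10.0


class NumericalError(RuntimeError):
    pass


@dataclass
class FitResult:
    logL: float
    parameters: dict
    n_free_params: int
    converged: bool
    n_iterations: int
    tree: PhyloTree | None = None
    model: object | None = None
    floored_branches: list[int] = field(default_factory=list)


@dataclass
class LRTResult:
    logL_null: float
    logL_alt: float
    statistic: float
    df: int
    p_value: float


class ReversibleMarkov:
    """P(t) for a reversible generator, via the symmetrized eigensystem."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        sq = np.sqrt(self.pi)
        B = sq[:, None] * Q / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._w = w
        self._U = U
        self._sq = sq

    def P(self, t: float) -> np.ndarray:
        E = self._U * np.exp(self._w * t)
        P = E @ self._U.T
        P = (P / self._sq[:, None]) * self._sq[None, :]
        np.clip(P, 0.0, None, out=P)
        return P


def _nuc_symbol_states() -> dict[str, np.ndarray]:
    base_idx = {b: i for i, b in enumerate("ACGT")}
    out = {}
    for sym, bases in IUPAC.items():
        v = np.zeros(4)
        for b in bases:
            v[base_idx[b]] = 1.0
        out[sym] = v
    return out


_SYMBOL_PARTIALS = _nuc_symbol_states()


class Peeler:
    """Reusable pruning machinery bound to one alignment/tree/model triple.

    Branch lengths are read from the tree at every call, so the same
    Peeler serves an entire optimization; call :meth:`refresh_model` after
    changing model parameters (exchangeabilities, frequencies, gamma,
    shared omega) and :meth:`refresh_branch_omega` after changing a single
    branch's omega.
    """

    def __init__(self, aln: Alignment | CodonAlignment, tree: PhyloTree, model):
        check_labels_match(tree, aln)
        self.tree = tree
        self.model = model
        self.is_codon = isinstance(model, CodonModelSpec)
        taxa_order = [aln.taxa.index(lb) for lb in tree.tip_labels()]

        if self.is_codon:
            data = aln.codon_sites[taxa_order]
        else:
            data = aln.sites[taxa_order]
        patterns, inverse, counts = np.unique(
            data, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_of_site = inverse
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]

        if self.is_codon:
            S = model.space.n_states
            tp = np.zeros((patterns.shape[0], self.n_patterns, S))
            miss = patterns == MISSING_CODON
            tp[miss] = 1.0
            rows, cols = np.where(~miss)
            tp[rows, cols, patterns[rows, cols]] = 1.0
        else:
            tp = np.empty((patterns.shape[0], self.n_patterns, 4))
            for r in range(patterns.shape[0]):
                for c in range(self.n_patterns):
                    tp[r, c] = _SYMBOL_PARTIALS[patterns[r, c]]
        self._tip_partials = {}
        for row, label in enumerate(tree.tip_labels()):
            self._tip_partials[tree.tip_index[label]] = tp[row]
        self.refresh_model()

    # -- model binding -----------------------------------------------------
    def refresh_model(self) -> None:
        model = self.model
        if self.is_codon:
            self.pi = model.codon_pi()
            self.rates, self.weights = rate_categories(model.nuc)
            self._omega_markov: dict[float, ReversibleMarkov] = {}
            self._branch_markov: dict[int, ReversibleMarkov] = {}
            for node in self.tree.branches():
                self._branch_markov[node.index] = self._markov_for_omega(
                    model.omega_for(node.index)
                )
        else:
            Q, self.rates, self.weights = build_nuc_Q(model)
            self.pi = model.pi
            mk = ReversibleMarkov(Q, self.pi)
            self._branch_markov = {n.index: mk for n in self.tree.branches()}

    def _markov_for_omega(self, omega: float) -> ReversibleMarkov:
        key = round(float(omega), 12)
        mk = self._omega_markov.get(key)
        if mk is None:
            Q = build_mg94_Q(self.model, omega=omega)
            mk = ReversibleMarkov(Q, self.pi)
            self._omega_markov[key] = mk
        return mk

    def refresh_branch_omega(self, branch: int) -> None:
        self._branch_markov[branch] = self._markov_for_omega(
            self.model.omega_for(branch)
        )

    # -- likelihood --------------------------------------------------------
    def _category_site_logL(self, rate: float) -> np.ndarray:
        tree = self.tree
        npat = self.n_patterns
        logscale = np.zeros(npat)
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            if node.is_tip:
                partials[node.index] = self._tip_partials[node.index]
                continue
            part = None
            for child in node.children:
                t = max(child.length or 0.0, BRANCH_LENGTH_FLOOR) * rate
                P = self._branch_markov[child.index].P(t)
                msg = partials[child.index] @ P.T
                part = msg if part is None else part * msg
            m = part.max(axis=1)
            m[m <= 0] = 1.0
            part = part / m[:, None]
            with np.errstate(divide="ignore"):
                logscale += np.log(m)
            partials[node.index] = part
        root_like = partials[tree.root.index] @ self.pi
        with np.errstate(divide="ignore"):
            return np.log(root_like) + logscale

    def site_log_likelihoods(self) -> np.ndarray:
        per_cat = np.stack([self._category_site_logL(r) for r in self.rates])
        logw = np.log(self.weights)
        return logsumexp(per_cat + logw[:, None], axis=0)

    def log_likelihood(self) -> float:
        site = self.site_log_likelihoods()
        if not np.all(np.isfinite(site)):
            bad = int(np.argmin(np.isfinite(site)))
            sites = np.where(self.pattern_of_site == bad)[0]
            raise NumericalError(
                f"non-finite site log-likelihood at pattern {bad} (site {sites[:1]})"
            )
        return float(site @ self.counts)


def log_likelihood(aln, tree: PhyloTree, model) -> float:
    """Total alignment log-likelihood on the given tree under the model."""
    return Peeler(aln, tree, model).log_likelihood()


# ---------------------------------------------------------------------------
# optimization


def _count_free_branches(tree: PhyloTree) -> int:
    # under a reversible model only the sum of the two root-adjacent branch
    # lengths is identifiable, matching the unrooted count 2n-3
    n = len(tree.branches())
    return n - (1 if len(tree.root.children) == 2 else 0)


def _brent(objective, lo, hi, x0, xatol):
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    f0 = objective(x0)
    if res.fun <= f0:
        return float(res.x), float(res.fun)
    return float(x0), float(f0)


def _codon_n_free_params(spec: CodonModelSpec, tree: PhyloTree, per_branch_omega: bool) -> int:
    k = (spec.nuc.partition.classes - 1) + 9  # tyings + 3x4 frequencies
    k += len(tree.branches()) if per_branch_omega else 1
    k += _count_free_branches(tree)
    return k


def fit_branch_lengths(
    aln,
    tree: PhyloTree,
    model,
    fixed_topology: bool = True,
    *,
    optimize_theta: bool = False,
    optimize_alpha: bool = False,
    optimize_pinv: bool = False,
    optimize_omega: str | None = None,  # None | "shared" | "per_branch"
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    logl_tol: float = DEFAULT_LOGL_TOL,
    bl_tol: float = DEFAULT_BL_TOL,
) -> FitResult:
    """Maximum-likelihood branch lengths (and optional model parameters).

    Coordinate-wise bounded line search over branches, interleaved with
    scalar parameter updates, until the relative log-likelihood change
    falls below ``logl_tol``.  The log-likelihood never decreases across
    sweeps; ties in coordinate updates resolve in branch index order.
    """
    if not fixed_topology:
        raise NotImplementedError("topology search is out of scope; topology is an input")
    tree = tree.copy()
    model = model.copy()
    is_codon = isinstance(model, CodonModelSpec)
    if is_codon and optimize_omega == "per_branch":
        for node in tree.branches():
            model.omega_map.setdefault(node.index, model.omega_shared)
    peeler = Peeler(aln, tree, model)

    def current() -> float:
        return peeler.log_likelihood()

    logL = current()
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        # branch lengths, in index order
        for node in tree.branches():
            def obj(t, node=node):
                node.length = t
                return -current()

            t_new, fval = _brent(obj, BRANCH_LENGTH_FLOOR, MAX_BRANCH_LENGTH,
                                 max(node.length or BRANCH_LENGTH_FLOOR, BRANCH_LENGTH_FLOOR),
                                 bl_tol)
            node.length = t_new
            if is_codon and optimize_omega == "per_branch":
                def obj_w(w, node=node):
                    model.omega_map[node.index] = w
                    peeler.refresh_branch_omega(node.index)
                    return -current()

                w_new, _ = _brent(obj_w, 0.0, 50.0, model.omega_map[node.index], 1e-5)
                model.omega_map[node.index] = w_new
                peeler.refresh_branch_omega(node.index)

        # scalar model parameters
        if is_codon and optimize_omega == "shared":
            def obj_w(w):
                model.omega_shared = w
                peeler.refresh_model()
                return -current()

            w_new, _ = _brent(obj_w, 0.0, 50.0, model.omega_shared, 1e-5)
            model.omega_shared = w_new
            peeler.refresh_model()
        nuc = model.nuc if is_codon else model
        if optimize_theta:
            for ci in nuc.free_theta_indices:
                def obj_th(logth, ci=ci):
                    nuc.theta[ci] = np.exp(logth)
                    peeler.refresh_model()
                    return -current()

                x_new, _ = _brent(obj_th, np.log(1e-4), np.log(1e4),
                                  np.log(nuc.theta[ci]), 1e-6)
                nuc.theta[ci] = np.exp(x_new)
                peeler.refresh_model()
        if optimize_alpha and nuc.gamma_shape is not None:
            def obj_a(loga):
                nuc.gamma_shape = np.exp(loga)
                peeler.refresh_model()
                return -current()

            x_new, _ = _brent(obj_a, np.log(0.02), np.log(100.0),
                              np.log(nuc.gamma_shape), 1e-6)
            nuc.gamma_shape = np.exp(x_new)
            peeler.refresh_model()
        if optimize_pinv and nuc.p_inv is not None:
            def obj_p(p):
                nuc.p_inv = p
                peeler.refresh_model()
                return -current()

            x_new, _ = _brent(obj_p, 0.0, 0.95, nuc.p_inv, 1e-6)
            nuc.p_inv = x_new
            peeler.refresh_model()

        new_logL = current()
        if new_logL < logL - 1e-6:
            logger.warning("log-likelihood decreased by %.3g in sweep %d",
                           logL - new_logL, sweeps)
        if abs(new_logL - logL) < logl_tol * (abs(logL) + 1.0):
            logL = new_logL
            converged = True
            break
        logL = new_logL

    floored = [n.index for n in tree.branches()
               if (n.length or 0.0) <= BRANCH_LENGTH_FLOOR * 2]
    k = _count_free_branches(tree)
    params: dict = {"branch_lengths": tree.branch_lengths()}
    if is_codon:
        k = _codon_n_free_params(model, tree, optimize_omega == "per_branch") \
            if optimize_omega else _codon_n_free_params(model, tree, False) - 1
        params["omega_shared"] = model.omega_shared
        params["omega_map"] = dict(model.omega_map)
        params["theta"] = model.nuc.theta.copy()
    else:
        k += model.n_free_params
        params["theta"] = model.theta.copy()
        params["alpha"] = model.gamma_shape
        params["p_inv"] = model.p_inv
    if not converged:
        logger.warning("branch-length fit hit max_sweeps=%d without converging", max_sweeps)
    return FitResult(
        logL=logL, parameters=params, n_free_params=k, converged=converged,
        n_iterations=sweeps, tree=tree, model=model, floored_branches=floored,
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass(frozen=True)
class NucModelFamily:
    """A nucleotide model family: exchangeability tying plus +G/+I flags."""

    pattern: str
    gamma: bool = False
    invariant: bool = False

    @property
    def label(self) -> str:
        suffix = ("+G" if self.gamma else "") + ("+I" if self.invariant else "")
        return self.pattern + suffix

    def instantiate(self, aln: Alignment) -> NucModelSpec:
        part = ExchangeabilityPartition(self.pattern)
        counts = np.array([(aln.sites == b).sum() for b in "ACGT"], dtype=float)
        pi = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
        return NucModelSpec(
            partition=part,
            theta=np.ones(part.classes),
            pi=pi,
            gamma_shape=1.0 if self.gamma else None,
            p_inv=0.1 if self.invariant else None,
        )


DEFAULT_NUC_CANDIDATES = (
    NucModelFamily("000000"),               # JC/F81-like
    NucModelFamily("010010"),               # HKY-like (transitions tied)
    NucModelFamily("012345"),               # GTR
    NucModelFamily("010010", gamma=True),
    NucModelFamily("012345", gamma=True),
    NucModelFamily("012345", gamma=True, invariant=True),
)


def select_nuc_model_bic(
    aln: Alignment,
    tree: PhyloTree,
    partition_map,
    candidates=DEFAULT_NUC_CANDIDATES,
    *,
    max_sweeps: int = 20,
) -> dict:
    """Per-partition BIC selection among nucleotide model families.

    Returns ``{partition_name: {"best": FitResult, "family": NucModelFamily,
    "table": records}}``.  BIC = -2 logL + k ln(n_sites); ties break by
    fewer parameters, then lexicographic label.
    """
    if not candidates:
        raise ValueError("need at least one candidate model family")
    results = {}
    for part in partition_map.partitions:
        if part.length == 0:
            raise ValueError(f"empty partition {part.name}")
        sub = aln.subset_sites(np.arange(part.start, part.end))
        rows = []
        for fam in candidates:
            spec = fam.instantiate(sub)
            fit = fit_branch_lengths(
                sub, tree, spec,
                optimize_theta=spec.partition.classes > 1,
                optimize_alpha=fam.gamma, optimize_pinv=fam.invariant,
                max_sweeps=max_sweeps,
            )
            bic = -2.0 * fit.logL + fit.n_free_params * np.log(part.length)
            rows.append({"family": fam, "label": fam.label, "logL": fit.logL,
                         "k": fit.n_free_params, "BIC": bic, "fit": fit})
        best = min(rows, key=lambda r: (round(r["BIC"], 9), r["k"], r["label"]))
        for r in rows:
            r["delta_BIC"] = r["BIC"] - best["BIC"]
        results[part.name] = {"best": best["fit"], "family": best["family"], "table": rows}
    return results


def select_codon_variant_aic(
    codon_aln: CodonAlignment,
    tree: PhyloTree,
    variants=None,
    *,
    per_branch_omega_scan: bool = False,
    refit_winner_per_branch: bool = True,
    max_sweeps: int = 8,
    winner_max_sweeps: int = 40,
) -> dict:
    """AIC selection among the MG94 exchangeability-tying variants.

    By default the 203-variant scan scores each variant with a single
    shared omega (the fast mode); the winner is then refit with one free
    omega per branch.  Pass ``per_branch_omega_scan=True`` to score every
    variant with per-branch omega.  Returns ``{"best_fit", "best_variant",
    "table"}`` where the table has one record per variant.
    """
    from claderates.substitution_models import enumerate_exchangeability_partitions

    if variants is None:
        variants = enumerate_exchangeability_partitions()
    freqs = CodonFreqs3x4.from_counts(codon_aln.position_base_counts(), pseudocount=1.0)
    omega_mode = "per_branch" if per_branch_omega_scan else "shared"
    rows = []
    for var in variants:
        nuc = NucModelSpec(partition=var, theta=np.ones(var.classes), pi=np.full(4, 0.25))
        spec = CodonModelSpec(nuc=nuc, freqs=freqs, omega_shared=0.5,
                              genetic_code=codon_aln.genetic_code)
        fit = fit_branch_lengths(
            codon_aln, tree, spec,
            optimize_theta=var.classes > 1, optimize_omega=omega_mode,
            max_sweeps=max_sweeps,
        )
        aic = -2.0 * fit.logL + 2.0 * fit.n_free_params
        rows.append({"variant": var, "label": var.label(), "logL": fit.logL,
                     "k": fit.n_free_params, "AIC": aic, "fit": fit})
    best = min(rows, key=lambda r: (round(r["AIC"], 9), r["variant"].classes, r["label"]))
    for r in rows:
        r["delta_AIC"] = r["AIC"] - best["AIC"]
    best_fit = best["fit"]
    if refit_winner_per_branch and not per_branch_omega_scan:
        spec = best_fit.model.copy()
        best_fit = fit_branch_lengths(
            codon_aln, tree, spec,
            optimize_theta=spec.nuc.partition.classes > 1,
            optimize_omega="per_branch", max_sweeps=winner_max_sweeps,
        )
    return {"best_fit": best_fit, "best_variant": best["variant"], "table": rows}


# ---------------------------------------------------------------------------
# constant-rates vs free-rates LRT


def fit_clock(
    aln,
    tree: PhyloTree,
    model,
    *,
    branch_scale: dict[int, float] | None = None,
    max_iter: int = 300,
) -> FitResult:
    """Strict-clock fit: equal root-to-tip path lengths, n-1 free node heights.

    Heights are parameterized as non-negative increments above the deeper
    child, guaranteeing ultrametricity.  ``branch_scale`` optionally maps
    branch ids to per-unit-time rate factors, so the clock constraint can
    be imposed on a derived quantity (e.g. nonsynonymous length) instead
    of raw time.
    """
    if tree.n_tips < 3:
        raise ValueError("clock test needs at least 3 tips")
    tree = tree.copy()
    if not tree.is_binary():
        raise ValueError("clock fit requires a binary rooted tree")
    model = model.copy()
    scale = branch_scale or {}
    internal = [n for n in tree.postorder if not n.is_tip]
    peeler = Peeler(aln, tree, model)

    # initial heights in annotation units from the current branch lengths
    height = np.zeros(len(tree.postorder))
    for n in tree.postorder:
        if not n.is_tip:
            height[n.index] = max(
                height[c.index] + max(c.length or 0.0, BRANCH_LENGTH_FLOOR)
                * scale.get(c.index, 1.0)
                for c in n.children
            )
    x0 = np.array([
        height[n.index] - max(height[c.index] for c in n.children) for n in internal
    ])
    x0 = np.maximum(x0, 1e-8)

    def apply(x: np.ndarray) -> None:
        h = np.zeros(len(tree.postorder))
        for k, n in enumerate(internal):
            h[n.index] = max(h[c.index] for c in n.children) + x[k]
        for n in tree.branches():
            dt = h[n.parent.index] - h[n.index]
            n.length = max(dt / scale.get(n.index, 1.0), BRANCH_LENGTH_FLOOR)

    def objective(x: np.ndarray) -> float:
        apply(x)
        return -peeler.log_likelihood()

    res = minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(0.0, None)] * len(x0),
        options={"maxiter": max_iter, "ftol": 1e-12},
    )
    apply(res.x)
    logL = -float(res.fun)
    return FitResult(
        logL=logL,
        parameters={"heights_increments": res.x, "branch_lengths": tree.branch_lengths()},
        n_free_params=len(x0),
        converged=bool(res.success),
        n_iterations=int(res.nit),
        tree=tree, model=model,
    )


def constant_vs_free_rates_lrt(
    aln,
    tree: PhyloTree,
    model,
    *,
    branch_scale: dict[int, float] | None = None,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> LRTResult:
    """Likelihood-ratio test of a strict clock against free branch lengths.

    The null has n-1 node-height parameters; the alternative has the 2n-3
    identifiable branch lengths, so df = n-2.  The p-value is from the
    chi-square distribution with that df.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError("LRT needs at least 3 tips")
    null = fit_clock(aln, tree, model, branch_scale=branch_scale)
    alt = fit_branch_lengths(aln, tree, model, max_sweeps=max_sweeps)
    stat = 2.0 * (alt.logL - null.logL)
    if stat < -1e-6:
        logger.warning("LRT statistic %.4g is negative beyond tolerance", stat)
    stat = max(stat, 0.0)
    df = n - 2
    return LRTResult(
        logL_null=null.logL, logL_alt=alt.logL, statistic=stat, df=df,
        p_value=float(chi2.sf(stat, df)),
    )
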