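"""Sister-pair definitions, validation against a tree, and path-length contrasts.

A sister pair is two clades that are each other's closest relatives, so
both lineages have had the same time to accumulate species and
substitutions.  Pairs are curated inputs; this module checks them against
the fitted topology (each side monophyletic, their union monophyletic,
pairs mutually non-overlapping) and extracts per-lineage path lengths
from the pair's common ancestor to the representative tip(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from claderates.data_io import PhyloTree


@dataclass
class SisterPairDef:
    """One sister pair: tip sets, species richness and representatives per side."""

    pair_id: str
    rich_tips: frozenset[str]
    poor_tips: frozenset[str]
    richness_rich: int
    richness_poor: int
    rep_rich: tuple[str, ...] = ()
    rep_poor: tuple[str, ...] = ()

    def __post_init__(self):
        self.rich_tips = frozenset(self.rich_tips)
        self.poor_tips = frozenset(self.poor_tips)
        if self.rich_tips & self.poor_tips:
            raise ValueError(f"pair {self.pair_id}: tip sets overlap")
        if min(self.richness_rich, self.richness_poor) < 1:
            raise ValueError(f"pair {self.pair_id}: richness must be >= 1")
        if not self.rep_rich:
            self.rep_rich = tuple(sorted(self.rich_tips))
        if not self.rep_poor:
            self.rep_poor = tuple(sorted(self.poor_tips))

    @property
    def all_tips(self) -> frozenset[str]:
        return self.rich_tips | self.poor_tips

    @property
    def equal_richness(self) -> bool:
        return self.richness_rich == self.richness_poor


@dataclass
class PairContrast:
    """A single signed contrast: species-rich value minus species-poor value."""

    pair_id: str
    value_rich: float
    value_poor: float
    metric: str = "total"

    @property
    def diff(self) -> float:
        return self.value_rich - self.value_poor


@dataclass
class PairValidationReport:
    retained: list[SisterPairDef] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (pair_id, reason)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def validate_pairs(tree: PhyloTree, pairs: list[SisterPairDef]) -> PairValidationReport:
    """Check monophyly and phylogenetic independence of every pair.

    A pair is retained only if each side is monophyletic in the tree, the
    union of the two sides is monophyletic (the sides are each other's
    closest relatives), and it shares no tips with any other pair.
    Exclusion is order-independent: overlap flags both offenders.
    """
    tip_set = set(tree.tip_index)
    for p in pairs:
        unknown = p.all_tips - tip_set
        if unknown:
            raise KeyError(f"pair {p.pair_id}: tips not in tree: {sorted(unknown)}")

    overlap_ids: set[str] = set()
    for i, a in enumerate(pairs):
        for b in pairs[i + 1:]:
            if a.all_tips & b.all_tips:
                overlap_ids.update((a.pair_id, b.pair_id))

    report = PairValidationReport()
    for p in pairs:
        if p.pair_id in overlap_ids:
            report.excluded.append((p.pair_id, "overlap"))
            continue
        reason = None
        for side, tips in (("rich", p.rich_tips), ("poor", p.poor_tips)):
            if tree.leaf_set(tree.mrca(tips)) != tips:
                reason = f"{side} side not monophyletic"
                break
        if reason is None and tree.leaf_set(tree.mrca(p.all_tips)) != p.all_tips:
            reason = "union not monophyletic"
        if reason:
            report.excluded.append((p.pair_id, reason))
        else:
            report.retained.append(p)
    return report


def choose_representative(
    clade: set[str],
    coverage: dict[str, int],
    seed: int = 0,
    n: int = 1,
) -> tuple[str, ...]:
    """Pick the representative tip(s) with greatest gene coverage.

    Ties in coverage are broken by a seeded uniform random choice, so the
    pick is reproducible.  ``n`` > 1 returns several top-coverage tips
    (closely related genera combined into one lineage).
    """
    if not clade:
        raise ValueError("empty clade")
    rng = np.random.default_rng(seed)
    ordered = sorted(clade)
    cov = np.array([coverage.get(t, 0) for t in ordered])
    chosen: list[str] = []
    remaining = list(range(len(ordered)))
    for _ in range(min(n, len(ordered))):
        best = max(cov[i] for i in remaining)
        ties = [i for i in remaining if cov[i] == best]
        pick = int(rng.choice(ties))
        chosen.append(ordered[pick])
        remaining.remove(pick)
    return tuple(chosen)


def pair_path_length(
    tree: PhyloTree, pair: SisterPairDef, metric: str = "total"
) -> PairContrast:
    """Root-to-tip path lengths for both lineages of a validated pair.

    Each side's value is the sum of branch lengths from the pair's common
    ancestor down to the representative tip; multi-tip representatives are
    averaged so lineages with different numbers of representatives stay
    comparable.  The signed difference is always rich minus poor.
    """
    mrca = tree.mrca(pair.all_tips)
    values = []
    for reps in (pair.rep_rich, pair.rep_poor):
        paths = [tree.path_to_ancestor(t, mrca) for t in reps]
        values.append(float(np.mean(paths)))
    return PairContrast(pair.pair_id, values[0], values[1], metric)


def read_pairs_table(path) -> list[SisterPairDef]:
    """Pairs TSV: pair_id, side in {rich, poor}, tip_labels (';'-joined), species_richness."""
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "side", "tip_labels", "species_richness"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    pairs = []
    for pid, grp in df.groupby("pair_id", sort=False):
        sides = {str(r["side"]): r for _, r in grp.iterrows()}
        if set(sides) != {"rich", "poor"}:
            raise ValueError(f"pair {pid}: need exactly one rich and one poor row")
        pairs.append(SisterPairDef(
            pair_id=str(pid),
            rich_tips=frozenset(str(sides["rich"]["tip_labels"]).split(";")),
            poor_tips=frozenset(str(sides["poor"]["tip_labels"]).split(";")),
            richness_rich=int(sides["rich"]["species_richness"]),
            richness_poor=int(sides["poor"]["species_richness"]),
        ))
    return pairs


def write_pairs_table(pairs: list[SisterPairDef], path) -> None:
    rows = []
    for p in pairs:
        rows.append((p.pair_id, "rich", ";".join(sorted(p.rich_tips)), p.richness_rich))
        rows.append((p.pair_id, "poor", ";".join(sorted(p.poor_tips)), p.richness_poor))
    pd.DataFrame(rows, columns=["pair_id", "side", "tip_labels", "species_richness"]) \
        .to_csv(path, sep="\t", index=False)


def contrast_table(
    trees: dict[str, PhyloTree], pairs: list[SisterPairDef]
) -> pd.DataFrame:
    """Wide per-pair table of rich/poor values for each metric tree.

    ``trees`` maps metric names (e.g. total, dN, dS) to trees sharing the
    topology the pairs were validated against.  An ``omega_rich/poor``
    column pair is added when both dN and dS trees are present, as the
    ratio of summed path lengths (path dN and path dS summed first, then
    divided).
    """
    from claderates.dnds_decomposition import omega_ratio

    rows = []
    for p in pairs:
        row: dict = {
            "pair_id": p.pair_id,
            "richness_rich": p.richness_rich,
            "richness_poor": p.richness_poor,
        }
        for metric, tree in trees.items():
            c = pair_path_length(tree, p, metric)
            row[f"{metric}_rich"] = c.value_rich
            row[f"{metric}_poor"] = c.value_poor
        if "dN" in trees and "dS" in trees:
            row["omega_rich"] = omega_ratio(row["dN_rich"], row["dS_rich"]).value
            row["omega_poor"] = omega_ratio(row["dN_poor"], row["dS_poor"]).value
        rows.append(row)
    return pd.DataFrame(rows)
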