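"""Reference-tree purging of candidate marker sequences.

Homology search alone recruits paralogs: sequences that look like a marker
gene but sit, on a curated reference phylogeny, in clades with no known
functional representatives (e.g. the non-functional cluster IV of the nifH
tree, or the hzsA-III cluster recruited by non-anammox organisms).  Each
query's phylogenetic placement is resolved to the smallest labelled clade
containing its best placement edge; curator-supplied rules (or the tree's
own functional / non_functional clade labels) decide retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import FeatureRecord
from .errors import ReferenceLookupError, ValidationError
from .io import Placement, PlacementSet, ReferenceTree

LOW_CONFIDENCE = "low_confidence"
NO_TREE = "no_tree"


@dataclass(frozen=True)
class FilterRule:
    gene: str
    clade_name: str
    verdict: str  # "retain" | "discard"

    def __post_init__(self) -> None:
        if self.verdict not in ("retain", "discard"):
            raise ValidationError(f"unknown verdict {self.verdict!r}")


@dataclass
class FilterReport:
    """Per-gene tally of the purge; counts always conserve."""

    gene: str
    n_input: int = 0
    n_retained: int = 0
    n_discarded: int = 0
    per_clade: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_retained + self.n_discarded != self.n_input:
            raise AssertionError(f"count conservation violated for {self.gene}")


def rules_from_tree(tree: ReferenceTree) -> list[FilterRule]:
    """Default rules: functional clades retain, non_functional discard."""
    return [
        FilterRule(tree.gene, name, "retain" if label == "functional" else "discard")
        for name, label in sorted(tree.clade_labels.items())
    ]


def _rule_map(rules: list[FilterRule], gene: str) -> dict[str, str]:
    return {r.clade_name: r.verdict for r in rules if r.gene == gene}


def classify_query(
    placements: list[Placement],
    tree: ReferenceTree,
    rules: list[FilterRule],
    weight_threshold: float = 0.5,
) -> tuple[str, str]:
    """Verdict for one query: (verdict, clade-or-reason).

    The query inherits the verdict of the smallest labelled clade containing
    its best placement edge (maximal like_weight_ratio; among tied
    placements the verdict breaks toward discard).  A best weight below
    ``weight_threshold`` discards with reason "low_confidence".
    """
    if not 0.0 < weight_threshold <= 1.0:
        raise ValidationError("weight_threshold must be in (0, 1]")
    if not placements:
        raise ValidationError("classify_query needs at least one placement")
    best_w = max(p.like_weight_ratio for p in placements)
    if best_w < weight_threshold:
        return "discard", LOW_CONFIDENCE
    verdict_map = _rule_map(rules, tree.gene)
    candidates = []
    for p in placements:
        if p.like_weight_ratio == best_w:
            clade = tree.smallest_labelled_clade(p.edge_ref)
            try:
                verdict = verdict_map[clade]
            except KeyError:
                raise ReferenceLookupError(
                    f"no rule for clade {clade!r} of gene {tree.gene}"
                )
            candidates.append((verdict, clade))
    # ties toward discard: a purge errs on the conservative side
    for verdict, clade in candidates:
        if verdict == "discard":
            return "discard", clade
    return candidates[0]


def filter_feature_table(
    records: list[FeatureRecord],
    placement_sets: dict[str, PlacementSet],
    trees: dict[str, ReferenceTree],
    rules: list[FilterRule] | None = None,
    weight_threshold: float = 0.5,
) -> tuple[list[FeatureRecord], dict[str, FilterReport]]:
    """Purge records whose queries classify as paralogs.

    ``placement_sets`` and ``trees`` are keyed by gene.  A gene without a
    tree is retained wholesale (reason "no_tree").  A record whose gene has
    a tree but whose orf_id has no placement is an error: every candidate
    the annotation pipeline emits for a tree-bearing gene must have been
    placed.
    """
    for gene in placement_sets:
        if gene not in trees:
            raise ReferenceLookupError(f"placements reference unknown gene {gene!r}")
    if rules is None:
        rules = [r for t in trees.values() for r in rules_from_tree(t)]

    by_gene_query: dict[str, dict[str, list[Placement]]] = {
        gene: ps.by_query() for gene, ps in placement_sets.items()
    }
    verdict_cache: dict[tuple[str, str], tuple[str, str]] = {}
    reports: dict[str, FilterReport] = {}
    retained: list[FeatureRecord] = []

    for rec in records:
        rep = reports.setdefault(rec.gene, FilterReport(gene=rec.gene))
        rep.n_input += 1
        if rec.gene not in trees:
            rep.n_retained += 1
            rep.per_clade[NO_TREE] = rep.per_clade.get(NO_TREE, 0) + 1
            retained.append(rec)
            continue
        key = (rec.gene, rec.orf_id)
        if key not in verdict_cache:
            qplace = by_gene_query.get(rec.gene, {}).get(rec.orf_id)
            if not qplace:
                raise ReferenceLookupError(
                    f"orf {rec.orf_id} ({rec.gene}) has a reference tree but no placement"
                )
            verdict_cache[key] = classify_query(
                qplace, trees[rec.gene], rules, weight_threshold
            )
        verdict, clade = verdict_cache[key]
        rep.per_clade[clade] = rep.per_clade.get(clade, 0) + 1
        if verdict == "retain":
            rep.n_retained += 1
            retained.append(rec)
        else:
            rep.n_discarded += 1

    for rep in reports.values():
        rep.check()
    return retained, reports
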