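"""Distance-based phylogeny, clade assignment, and habitat tabulation.

Detected rhodopsins are placed among labeled references with a
neighbor-joining tree built from alignment-based p-distances (optionally
Poisson-corrected), with classical column-bootstrap support on internal
edges. A query is assigned to the clade of its nearest reference only if it
also falls inside that clade's smallest spanning subtree and the subtending
edge is supported at >= 50% — queries failing either check stay unassigned.
Finally the survey is summarized as a habitat x clade table: gene counts per
clade and rhodopsin-possessing genome counts per habitat, stratified by
genomic subclade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .fileio import FastaRecord, ValidationError
from .screen import AlignmentParams, align_pair

logger = logging.getLogger("cyrpipe")

HABITATS = ("marine", "freshwater", "saline", "NA")
SUBCLADES = ("A", "B", "C", "D", "E", "F", "G", "NA")
CLADES = ("XLR", "NaR", "XeR", "CyHR", "CyR")

#: display/assignment threshold on bootstrap support (percent)
SUPPORT_THRESHOLD = 50.0


@dataclass(frozen=True)
class GenomeRecord:
    """A surveyed genome: habitat metadata plus its detected rhodopsin genes."""

    genome_id: str
    subclade: str = "NA"
    habitat: str = "NA"
    diox1_present: bool = True
    rhodopsins: tuple[tuple[str, str], ...] = ()  # (gene_id, clade_label)


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    clade_label: str  # one of CLADES or "unassigned"
    support: float | None
    method_detail: Mapping[str, object]


# ---------------------------------------------------------------------------
# distances


def _pair_pdistance(a: str, b: str, params: AlignmentParams, names=("a", "b")) -> float:
    aln = align_pair(a, b, params)
    n = diff = 0
    for qa, qb in zip(aln.aligned_query, aln.aligned_reference):
        if qa != "-" and qb != "-":
            n += 1
            diff += qa != qb
    if n == 0:
        raise ValidationError(f"no gap-free overlap between {names[0]!r} and {names[1]!r}")
    return diff / n


def _correct(p: np.ndarray, correction: str) -> np.ndarray:
    if correction == "none":
        return p
    if correction == "poisson":
        if np.any(p >= 1.0):
            raise ValidationError("p-distance saturated (p >= 1); Poisson correction undefined")
        return -np.log1p(-p)
    raise ValidationError(f"unknown distance correction: {correction!r}")


def pdistance_matrix(
    sequences: Sequence[FastaRecord],
    params: AlignmentParams = AlignmentParams(),
    correction: str = "none",
) -> DistanceMatrix:
    """Pairwise p-distances (mismatch fraction over gap-free aligned columns).

    ``correction="poisson"`` applies -ln(1 - p) for multiple hits.
    """
    if len(sequences) < 3:
        raise ValidationError("need at least 3 sequences for a distance matrix")
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_pdistance(
                sequences[i].seq,
                sequences[j].seq,
                params,
                (sequences[i].id, sequences[j].id),
            )
    d = _correct(d, correction)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [r.id for r in sequences])


#: stacking scoring: end gaps penalized (every stacked sequence is a
#: full-length homolog) and stiff gap costs, so chance off-diagonal
#: similarity between distant clades cannot mis-register a sequence against
#: the anchor; genuine short loops still align as gaps
STACKING_PARAMS = AlignmentParams(gap_open=20.0, gap_extend=2.0, mode="global_strict")


def anchor_alignment(
    sequences: Sequence[FastaRecord],
    anchor_id: str,
    params: AlignmentParams | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Reference-anchored stacked alignment.

    Every sequence is aligned pairwise to the anchor; rows are the residues
    seen at each anchor column ('-' where a sequence gaps out). Insertions
    relative to the anchor are dropped. This is the columns view used for
    bootstrap resampling; it is indel-light by design and documented as such.
    """
    if params is None:
        params = STACKING_PARAMS
    by_id = {r.id: r for r in sequences}
    if anchor_id not in by_id:
        raise ValidationError(f"anchor {anchor_id!r} not among sequences")
    anchor = by_id[anchor_id].seq
    # full-length homologs: never use free end gaps for stacking
    from dataclasses import replace as _dc_replace

    if params.mode == "global":
        params = _dc_replace(params, mode="global_strict")
    rows = []
    labels = []
    for rec in sequences:
        row = ["-"] * len(anchor)
        aln = align_pair(rec.seq, anchor, params)
        apos = 0
        for qc, ac in zip(aln.aligned_query, aln.aligned_reference):
            if ac != "-":
                row[apos] = qc
                apos += 1
        rows.append(row)
        labels.append(rec.id)
    return np.array(rows, dtype="<U1"), labels


def aligned_pdistance(
    matrix: np.ndarray, labels: Sequence[str], correction: str = "none"
) -> DistanceMatrix:
    """p-distances from a stacked alignment matrix (rows = sequences)."""
    n = matrix.shape[0]
    d = np.zeros((n, n))
    gapfree = matrix != "-"
    for i in range(n):
        for j in range(i + 1, n):
            both = gapfree[i] & gapfree[j]
            if not both.any():
                raise ValidationError(
                    f"no gap-free overlap between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = np.mean(matrix[i, both] != matrix[j, both])
    d = _correct(d, correction)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(labels))


# ---------------------------------------------------------------------------
# trees


def nj_build(dm: DistanceMatrix):
    """Neighbor joining; negative branch lengths are clamped to 0 and logged."""
    if dm.shape[0] < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(dm, neg_as_zero=False)
    deficit = 0.0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            deficit += -node.length
            node.length = 0.0
    if deficit > 0:
        logger.warning("clamped negative NJ branch lengths (total deficit %.4g)", deficit)
    return tree


def bipartitions(tree) -> dict[frozenset, object]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized.

    Each internal edge splits the taxa in two; the side NOT containing the
    lexicographically smallest taxon is the canonical key. Maps each
    bipartition to the tree node subtending it.
    """
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    out: dict[frozenset, object] = {}
    for node in tree.traverse():
        if node.is_tip() or node.parent is None:
            continue
        side = frozenset(t.name for t in node.tips())
        canon = side if anchor not in side else taxa - side
        if 2 <= len(canon) <= len(taxa) - 2:
            out[canon] = node
    return out


def bootstrap_support(
    alignment: np.ndarray,
    labels: Sequence[str],
    n_replicates: int = 100,
    seed: int | None = None,
    correction: str = "none",
):
    """NJ tree with classical column-bootstrap supports on internal edges.

    Columns of the stacked alignment are resampled with replacement
    ``n_replicates`` times; the support of an internal edge is the percentage
    of replicate trees containing its bipartition. Rows are sorted by label
    first so supports do not depend on input order.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    order = np.argsort(labels)
    alignment = alignment[order]
    labels = [labels[i] for i in order]

    tree = nj_build(aligned_pdistance(alignment, labels, correction))
    parts = bipartitions(tree)
    counts = {p: 0 for p in parts}

    rng = np.random.default_rng(seed)
    ncols = alignment.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, ncols)
        try:
            rep_dm = aligned_pdistance(alignment[:, cols], labels, correction)
        except ValidationError:  # resample lost all shared columns for a pair
            continue
        rep_parts = bipartitions(nj_build(rep_dm))
        for p in counts:
            if p in rep_parts:
                counts[p] += 1

    for p, node in parts.items():
        node.support = 100.0 * counts[p] / n_replicates
    return tree


def assign_clade(
    query_ids: Sequence[str],
    panel: Mapping[str, str],
    tree,
    dm: DistanceMatrix,
    support_threshold: float = SUPPORT_THRESHOLD,
    max_distance_ratio: float = 1.5,
    distance_slack: float = 0.02,
) -> list[CladeAssignment]:
    """Assign each query to the clade of its nearest reference, with checks.

    The nearest-reference call stands only if (i) it is not tied between two
    clades, (ii) the query lies inside the clade's subtree in the NJ tree —
    the maximal monophyletic group containing every reference of that clade
    and no reference of any other clade — and (iii) that subtree's subtending
    edge has bootstrap support >= the threshold (edges without a support
    value pass, so the check degrades gracefully on un-bootstrapped trees).
    Otherwise the query is reported unassigned. The maximal group is used
    because references rarely span every internal branch of their clade: the
    literal minimal spanning subtree of the references would exclude genuine
    clade members attached between reference branches.

    A distance gate backs up the topology check: the query's distance to its
    nearest reference must not exceed ``max_distance_ratio`` times the
    clade's reference diameter (max pairwise reference distance) plus
    ``distance_slack``. Long-branch outliers can attach adjacent to a clade
    in the tree, where no topological criterion excludes them; their
    distances give them away.
    """
    clade_refs: dict[str, list[str]] = {}
    for ref_id, clade in panel.items():
        clade_refs.setdefault(clade, []).append(ref_id)
    for clade, refs in clade_refs.items():
        if len(refs) < 2:
            raise ValidationError(f"clade {clade!r} needs >= 2 panel references")

    taxa = frozenset(t.name for t in tree.tips())
    parts = bipartitions(tree)
    # both orientations of every edge are candidate "sides"
    sides: list[tuple[frozenset, object]] = []
    for canon, node in parts.items():
        sides.append((canon, node))
        sides.append((taxa - canon, node))

    out: list[CladeAssignment] = []
    for qid in query_ids:
        dists = sorted((dm[qid, rid], rid) for rid in panel)
        best_d, best_ref = dists[0]
        clade = panel[best_ref]
        tie = any(
            abs(d - best_d) < 1e-9 and panel[rid] != clade for d, rid in dists[1:]
        )
        detail: dict[str, object] = {
            "nearest_reference": best_ref,
            "nearest_distance": best_d,
            "tie": tie,
        }
        if tie:
            out.append(CladeAssignment(qid, "unassigned", None, detail))
            continue
        refset = set(clade_refs[clade])
        diameter = max(
            dm[a, b] for a in refset for b in refset if a != b
        )
        gate = max_distance_ratio * diameter + distance_slack
        detail["distance_gate"] = gate
        if best_d > gate:
            detail["monophyly"] = None  # distance gate failed before topology
            out.append(CladeAssignment(qid, "unassigned", None, detail))
            continue
        foreign = set(panel) - refset
        spanning = [
            (len(side), side, node)
            for side, node in sides
            if refset <= side and not (side & foreign) and len(side) < len(taxa)
        ]
        if not spanning:
            detail["monophyly"] = False
            out.append(CladeAssignment(qid, "unassigned", None, detail))
            continue
        size, side, node = max(spanning, key=lambda x: x[0])
        support = getattr(node, "support", None)
        inside = qid in side
        supported = support is None or support >= support_threshold
        detail["monophyly"] = inside
        detail["spanning_subtree_size"] = size
        if inside and supported:
            out.append(CladeAssignment(qid, clade, support, detail))
        else:
            out.append(CladeAssignment(qid, "unassigned", support, detail))
    return out


# ---------------------------------------------------------------------------
# habitat x clade tabulation


def tabulate_habitat(records: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Survey summary table: one row per subclade plus a Total row.

    Columns: rhodopsin-possessing genome count; gene counts per clade and
    their total; possessing-genome counts per habitat; all-genome count.
    Clade columns count genes; habitat columns count genomes with >= 1
    rhodopsin. Row/column sum invariants hold by construction.
    """
    for rec in records:
        if rec.habitat not in HABITATS:
            raise ValidationError(f"genome {rec.genome_id!r}: unknown habitat {rec.habitat!r}")
        if rec.subclade not in SUBCLADES:
            raise ValidationError(f"genome {rec.genome_id!r}: unknown subclade {rec.subclade!r}")
        for gene_id, clade in rec.rhodopsins:
            if clade not in CLADES:
                raise ValidationError(
                    f"genome {rec.genome_id!r} gene {gene_id!r}: unknown clade {clade!r}"
                )

    habitat_cols = {"marine": "Marine", "freshwater": "Freshwater", "saline": "Saline", "NA": "NA"}
    columns = (
        ["rhodopsin_possessing_genomes"]
        + list(CLADES)
        + ["gene_total"]
        + list(habitat_cols.values())
        + ["all_genomes"]
    )
    present = [s for s in SUBCLADES if any(r.subclade == s for r in records)]
    table = pd.DataFrame(0, index=present + ["Total"], columns=columns, dtype=int)
    for rec in records:
        row = rec.subclade
        table.loc[row, "all_genomes"] += 1
        if rec.rhodopsins:
            table.loc[row, "rhodopsin_possessing_genomes"] += 1
            table.loc[row, habitat_cols[rec.habitat]] += 1
            for _gene_id, clade in rec.rhodopsins:
                table.loc[row, clade] += 1
                table.loc[row, "gene_total"] += 1
    table.loc["Total"] = table.loc[present].sum(axis=0) if present else 0
    table.index.name = "subclade"
    return table
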