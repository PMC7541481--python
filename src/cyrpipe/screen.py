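"""Rhodopsin homolog detection and helix-C motif based function prediction.

Microbial rhodopsins are classified functionally by a handful of residues:
the proton acceptor / hydrogen-bond partner / proton donor triplet on helix C
(DTD in bacteriorhodopsin, where it is Asp85/Thr89/Asp96), the Schiff-base
lysine on helix G that covalently binds retinal (Lys216 in BR), the
counterion aspartate stabilizing the protonated Schiff base, and the
extracellular proton release pair of glutamates. This module detects
homologs in a proteome by pairwise alignment against a labeled reference
panel, maps those functional positions from reference numbering onto each
query, and predicts the transport function from an ordered rule table
(DTD/DTE + Schiff lysine -> outward proton pump; NDQ -> sodium pump; NTQ or
TSD -> inward chloride pump; acceptor without a carboxylic donor -> inward
proton pump; no Schiff lysine -> nonfunctional opsin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .fileio import FastaRecord, ValidationError

logger = logging.getLogger("cyrpipe")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: functional roles tracked at reference-numbered positions
ROLES = (
    "acceptor",
    "hbond_partner",
    "donor",
    "counterion",
    "release1",
    "release2",
    "schiff_lysine",
)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise protein alignment.

    A gap of length L costs ``gap_open + gap_extend * L``. ``mode`` is
    ``"global"`` (global with free end gaps, the screening default),
    ``"global_strict"`` (end gaps penalized; used for anchor stacking where
    every sequence is a full-length homolog), or ``"local"``
    (Smith-Waterman).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mode: str = "global"

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap penalties must be positive")
        if self.mode not in ("global", "global_strict", "local"):
            raise ValidationError(f"unknown alignment mode: {self.mode!r}")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gapped query/reference strings with score and identity statistics.

    ``percent_identity`` is matches over all alignment columns excluding the
    terminal overhangs, so internal gap columns count against identity;
    indel-free homolog pairs are unaffected while gappy chance alignments of
    unrelated sequences are penalized.
    """

    aligned_query: str
    aligned_reference: str
    score: float
    percent_identity: float  # matches / core columns, in [0, 100]
    aligned_length: int  # columns with a residue in both sequences
    reference_coverage: float  # aligned_length / len(reference)


@dataclass(frozen=True)
class RhodopsinHit:
    """One detected rhodopsin gene in a proteome."""

    protein_id: str
    genome_id: str
    best_reference_id: str
    score: float
    percent_identity: float
    aligned_length: int


@dataclass(frozen=True)
class ReferenceMap:
    """Role -> position table on a reference, in a named numbering system.

    ``numbering_label`` records the convention the positions live in — e.g.
    ``"BR-mature"`` (acceptor at 85) or ``"scaffold"`` for synthetic panels —
    it is metadata, never inferred.
    """

    reference_id: str
    positions: Mapping[str, int]
    numbering_label: str = "scaffold"

    def __post_init__(self):
        pos = list(self.positions.values())
        if len(set(pos)) != len(pos):
            raise ValidationError("reference map positions must be distinct")
        if any(p < 1 for p in pos):
            raise ValidationError("reference map positions are 1-based (>= 1)")
        unknown = set(self.positions) - set(ROLES)
        if unknown:
            raise ValidationError(f"unknown roles in reference map: {sorted(unknown)}")


@dataclass(frozen=True)
class MotifCall:
    """Residues observed at the functional positions of one query."""

    motif_triplet: str  # acceptor, hbond_partner, donor ('-' for gap)
    schiff_lysine_present: bool
    counterion_residue: str
    release_pair: str
    query_positions: Mapping[str, int | None]  # 1-based in the unaligned query
    gaps: tuple[str, ...]


@dataclass(frozen=True)
class FunctionPrediction:
    label: str
    rule_id: str
    evidence: Mapping[str, object]


def _validate_protein(seq: str, name: str) -> None:
    bad = set(seq) - set(AMINO_ACIDS)
    if not seq:
        raise ValidationError(f"{name}: empty sequence")
    if bad:
        raise ValidationError(f"{name}: non-amino-acid characters {sorted(bad)}")


def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.mode = "local" if params.mode == "local" else "global"
    # first gapped residue costs open+extend, each further one costs extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if params.mode == "global":
        # attribute renamed across Biopython versions
        if hasattr(aligner, "open_end_gap_score"):
            aligner.open_end_gap_score = 0.0
            aligner.extend_end_gap_score = 0.0
        else:  # pragma: no cover
            aligner.end_open_gap_score = 0.0
            aligner.end_extend_gap_score = 0.0
    return aligner


def align_pair(
    query: str, reference: str, params: AlignmentParams = AlignmentParams()
) -> PairwiseAlignment:
    """Optimal pairwise alignment of two protein sequences.

    Traceback ties are resolved deterministically by taking the aligner's
    first optimal alignment (fixed for a given Biopython version), so motif
    positions are reproducible run to run.
    """
    _validate_protein(query, "query")
    _validate_protein(reference, "reference")
    aligner = _make_aligner(params)
    aln = aligner.align(query, reference)[0]
    gq, gr = str(aln[0]), str(aln[1])
    matches = aligned = 0
    for a, b in zip(gq, gr):
        if a != "-" and b != "-":
            aligned += 1
            if a == b:
                matches += 1
    # core region = alignment minus terminal overhangs
    lead = max(len(gq) - len(gq.lstrip("-")), len(gr) - len(gr.lstrip("-")))
    tail = max(len(gq) - len(gq.rstrip("-")), len(gr) - len(gr.rstrip("-")))
    core = len(gq) - lead - tail
    # unrelated sequences can align as disjoint end-gap blocks (score 0,
    # empty core); report identity 0 rather than erroring
    return PairwiseAlignment(
        aligned_query=gq,
        aligned_reference=gr,
        score=float(aln.score),
        percent_identity=100.0 * matches / core if core > 0 else 0.0,
        aligned_length=aligned,
        reference_coverage=aligned / len(reference),
    )


def screen_proteome(
    proteome: Sequence[FastaRecord],
    references: Sequence[FastaRecord],
    params: AlignmentParams = AlignmentParams(),
    min_identity: float = 25.0,
    min_coverage: float = 0.6,
    genome_id: str = "",
) -> list[RhodopsinHit]:
    """Detect rhodopsin homologs in a proteome against a reference panel.

    Each query is aligned to every reference; the best-scoring reference is
    kept and the query becomes a hit iff identity and reference coverage pass
    the thresholds. An empty proteome yields an empty result. The same
    routine screens for any reference family (e.g. a diox1 panel to flag
    retinal-biosynthesis capability).
    """
    if not references:
        raise ValidationError("reference panel is empty")
    hits: list[RhodopsinHit] = []
    for rec in proteome:
        best: tuple[float, FastaRecord, PairwiseAlignment] | None = None
        for ref in references:
            aln = align_pair(rec.seq, ref.seq, params)
            if best is None or aln.score > best[0]:
                best = (aln.score, ref, aln)
        assert best is not None
        _, ref, aln = best
        if aln.percent_identity >= min_identity and aln.reference_coverage >= min_coverage:
            hits.append(
                RhodopsinHit(
                    protein_id=rec.id,
                    genome_id=genome_id,
                    best_reference_id=ref.id,
                    score=aln.score,
                    percent_identity=aln.percent_identity,
                    aligned_length=aln.aligned_length,
                )
            )
    return hits


def extract_motif(
    query: str,
    reference: str,
    refmap: ReferenceMap,
    params: AlignmentParams = AlignmentParams(),
) -> MotifCall:
    """Report the query residues aligned to the reference's functional sites.

    Positions are returned in 1-based coordinates of the unaligned query.
    A role whose reference position aligns to a gap (or falls outside the
    aligned region) is reported as ``'-'`` and listed in ``gaps`` with a
    warning — not an error.
    """
    if max(refmap.positions.values()) > len(reference):
        raise ValidationError("reference map position outside reference length")
    aln = align_pair(query, reference, params)
    # column walk: reference position -> (query residue, query position)
    ref_to_query: dict[int, tuple[str, int | None]] = {}
    qpos = rpos = 0
    for qc, rc in zip(aln.aligned_query, aln.aligned_reference):
        if qc != "-":
            qpos += 1
        if rc != "-":
            rpos += 1
            ref_to_query[rpos] = (qc, qpos if qc != "-" else None)

    residues: dict[str, str] = {}
    positions: dict[str, int | None] = {}
    gaps: list[str] = []
    for role, rp in refmap.positions.items():
        res, qp = ref_to_query.get(rp, ("-", None))
        if res == "-":
            gaps.append(role)
            logger.warning("role %s aligned to a gap for this query", role)
        residues[role] = res
        positions[role] = qp

    triplet = (
        residues.get("acceptor", "-")
        + residues.get("hbond_partner", "-")
        + residues.get("donor", "-")
    )
    return MotifCall(
        motif_triplet=triplet,
        schiff_lysine_present=residues.get("schiff_lysine", "-") == "K",
        counterion_residue=residues.get("counterion", "-"),
        release_pair=residues.get("release1", "-") + residues.get("release2", "-"),
        query_positions=positions,
        gaps=tuple(gaps),
    )


# ---------------------------------------------------------------------------
# transport-function rule table

Rule = tuple[str, Callable[[MotifCall], bool], str]

_ACIDIC = "DE"


def _has_acceptor(c: MotifCall) -> bool:
    return c.motif_triplet[0] in _ACIDIC


def _has_donor(c: MotifCall) -> bool:
    return c.motif_triplet[2] in _ACIDIC


#: ordered rule table; the first matching rule fires. DTD/DTE precede the
#: chloride/sodium rules because proton pumps are the clade of interest.
DEFAULT_RULES: tuple[Rule, ...] = (
    ("no_schiff_lysine", lambda c: not c.schiff_lysine_present, "nonfunctional_opsin"),
    (
        "dtd_dte_proton_pump",
        lambda c: c.motif_triplet in ("DTD", "DTE") and _has_acceptor(c),
        "outward_H_pump",
    ),
    ("ndq_sodium_pump", lambda c: c.motif_triplet == "NDQ", "Na_pump"),
    (
        "chloride_pump",
        lambda c: c.motif_triplet == "NTQ" or c.motif_triplet == "TSD"
        or (c.motif_triplet[:2] == "TS" and not _has_acceptor(c)),
        "inward_Cl_pump",
    ),
    (
        "acceptor_no_donor",
        lambda c: _has_acceptor(c) and not _has_donor(c),
        "inward_H_pump",
    ),
    ("fallback", lambda c: True, "sensor_or_unknown"),
)


def predict_function(
    call: MotifCall, rules: Sequence[Rule] = DEFAULT_RULES
) -> FunctionPrediction:
    """Map a motif call to a transport-function label.

    Total by construction: the final fallback rule always fires, so every
    possible call maps to exactly one label (the first match in order).
    """
    for rule_id, predicate, label in rules:
        if predicate(call):
            return FunctionPrediction(
                label=label,
                rule_id=rule_id,
                evidence={
                    "motif_triplet": call.motif_triplet,
                    "schiff_lysine_present": call.schiff_lysine_present,
                    "counterion_residue": call.counterion_residue,
                    "release_pair": call.release_pair,
                },
            )
    raise AssertionError("rule table has no fallback")  # pragma: no cover
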