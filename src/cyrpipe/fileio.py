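"""File formats, run configuration, and manifests.

Formats touched by the pipeline:

* protein FASTA (Biopython-backed) for proteomes and reference panels;
* TSV for genome metadata, reference site maps, hit/motif reports and
  truth tables;
* CSV matrices for spectroscopy — first column is the wavelength in nm,
  the header row carries the second axis (time in ms, or pH);
* newick for trees (bootstrap supports as internal node labels);
* YAML for the run configuration, JSON for run manifests.

All residue positions in every on-disk report are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("cyrpipe")


class ValidationError(ValueError):
    """Raised for malformed inputs; mapped to exit code 2 by the CLI."""


@dataclass(frozen=True)
class FastaRecord:
    """A protein sequence with its FASTA id and free-text description."""

    id: str
    seq: str
    description: str = ""


def parse_fasta(source: str | Path | IO[str]) -> list[FastaRecord]:
    """Read protein FASTA (wrapped or unwrapped lines).

    Sequences are upper-cased; trailing ``*`` stop characters are stripped
    with a warning. Duplicate ids and empty sequences are errors.
    """
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            logger.warning("stripping '*' terminator from %s", rec.id)
            seq = seq.rstrip("*")
        if not seq:
            raise ValidationError(f"empty sequence for FASTA id: {rec.id!r}")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(FastaRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[FastaRecord], dest: str | Path | IO[str]) -> None:
    """Write records as 60-column wrapped FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seqrecords, dest, "fasta")


# ---------------------------------------------------------------------------
# spectroscopy matrices


def write_matrix_csv(
    path: str | Path,
    wavelengths: np.ndarray,
    axis: np.ndarray,
    matrix: np.ndarray,
    axis_name: str,
) -> None:
    """CSV matrix: first column wavelength (nm), header row = second axis."""
    df = pd.DataFrame(matrix, columns=[f"{v:g}" for v in axis])
    df.insert(0, f"wavelength_nm/{axis_name}", np.asarray(wavelengths))
    df.to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`write_matrix_csv`.

    Returns ``(wavelengths, axis_values, matrix)``.
    """
    df = pd.read_csv(path)
    wavelengths = df.iloc[:, 0].to_numpy(dtype=float)
    axis = np.array([float(c) for c in df.columns[1:]])
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    return wavelengths, axis, matrix


# ---------------------------------------------------------------------------
# reference site-map sidecar (reference_id, role, position, numbering_label)


def write_refmap_tsv(path: str | Path, refmaps: Sequence) -> None:
    rows = []
    for rm in refmaps:
        for role, pos in rm.positions.items():
            rows.append(
                {
                    "reference_id": rm.reference_id,
                    "role": role,
                    "position": pos,
                    "numbering_label": rm.numbering_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_refmap_tsv(path: str | Path) -> dict[str, "ReferenceMapLike"]:
    """Read the sidecar TSV into {reference_id: ReferenceMap}."""
    from .screen import ReferenceMap  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    out: dict[str, ReferenceMap] = {}
    for ref_id, grp in df.groupby("reference_id", sort=False):
        labels = set(grp["numbering_label"])
        if len(labels) != 1:
            raise ValidationError(f"inconsistent numbering_label for {ref_id!r}")
        out[str(ref_id)] = ReferenceMap(
            reference_id=str(ref_id),
            positions={str(r.role): int(r.position) for r in grp.itertuples()},
            numbering_label=labels.pop(),
        )
    return out


ReferenceMapLike = object  # typing alias resolved at runtime by read_refmap_tsv


# ---------------------------------------------------------------------------
# newick


def _quote_label(label: str) -> str:
    if any(c in label for c in " ():;,[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree) -> str:
    """Serialize a tree (skbio ``TreeNode``) to newick.

    Bootstrap supports (``node.support``, percentages) become internal node
    labels; branch lengths are written with 6 significant digits; leaf names
    containing spaces or newick metacharacters are quoted.
    """
    if tree is None or tree.count(tips=True) == 0:
        raise ValidationError("empty tree")

    def fmt(node) -> str:
        if node.is_tip():
            s = _quote_label(node.name or "")
        else:
            inner = ",".join(fmt(c) for c in node.children)
            support = getattr(node, "support", None)
            label = "" if support is None else f"{support:g}"
            s = f"({inner}){label}"
        if node.length is not None:
            s += f":{node.length:.6g}"
        return s

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    A single master seed drives every random stage: per-component substreams
    are spawned from it with ``numpy.random.SeedSequence`` so no stage reads
    system entropy.
    """

    seed: int = 0
    outdir: str = "run"
    references: str | None = None  # FASTA path; None -> synthetic panel
    metadata: str | None = None  # genome metadata TSV; None -> synthetic
    # synthetic generation
    n_genomes: int = 12
    genes_per_genome: int = 1
    decoys_per_genome: int = 4
    n_refs_per_clade: int = 3
    # alignment / screening
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_identity: float = 25.0
    min_coverage: float = 0.6
    # tree
    bootstrap_n: int = 100
    support_threshold: float = 50.0
    # photocycle
    flash_noise_sigma: float = 0.003
    # titration
    titration_noise_sigma: float = 0.002

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: str | Path, config: RunConfig, artifacts: Sequence[str]) -> dict:
    """Write the run manifest (config hash, seed, versions, artifact list)."""
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "cyrpipe_version": __version__,
        "numpy_version": np.__version__,
        "artifacts": sorted(artifacts),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
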