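"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the survey's input classes: (i) proteomes containing
clade-labeled rhodopsin homologs with planted helix-C motifs plus
non-rhodopsin decoys, (ii) flash-photolysis difference matrices on the
instrument grids (370-700 nm at 5 nm, 0.01-977 ms) produced by the
sequential photocycle model with Gaussian noise, and (iii) pH-titration
spectral series with a two-state protonation structure. Every emitted
protein or dataset carries exactly one ground-truth record; recovery tests
join on the truth table instead of re-deriving it.

Sequence model: a random scaffold (uniform over the 20 standard residues)
carries the functional-site map; each clade descends from its own founder
(a heavily mutated scaffold copy) and members are substitution-only mutants
of the founder, so site positions are exact. Motif and Schiff sites are
never mutated — except in decoys, which ablate the Schiff lysine. Indel
robustness is exercised separately via an "indel stress" option that
inserts short loops away from the mapped sites.

Every generator is a pure function of (arguments, seed): a master seed
spawns per-component substreams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fileio import FastaRecord, ValidationError
from .phylo import CLADES, HABITATS, GenomeRecord
from .photocycle import (
    DEFAULT_TIMES,
    DEFAULT_WAVELENGTHS,
    FlashDataset,
    PhotocycleModel,
    SpectralBand,
    synth_difference_spectra,
)
from .screen import AMINO_ACIDS, ROLES, ReferenceMap
from .titration import TitrationDataset, hh_occupancy

#: functional-site positions in mature-bacteriorhodopsin numbering
#: (acceptor Asp85, hbond partner Thr89, donor Asp96, release pair
#: Glu194/Glu204, counterion Asp212, Schiff-base Lys216)
BR_SITE_MAP: dict[str, int] = {
    "acceptor": 85,
    "hbond_partner": 89,
    "donor": 96,
    "release1": 194,
    "release2": 204,
    "counterion": 212,
    "schiff_lysine": 216,
}

#: the same roles in N2098R numbering (Asp74, Glu85 donor, Glu182/Glu192
#: release pair, Asp200 counterion, Lys204 Schiff base; the hydrogen-bond
#: partner is the helix-C acceptor+4 position)
N2098R_SITE_MAP: dict[str, int] = {
    "acceptor": 74,
    "hbond_partner": 78,
    "donor": 85,
    "release1": 182,
    "release2": 192,
    "counterion": 200,
    "schiff_lysine": 204,
}

#: generator defaults for pH-titration ground truth: the alkaline-side
#: (Schiff-base lysine) midpoint and an acid-side (acceptor) midpoint below
#: the reliably bracketable range of a grid starting at pH 1.00
DEFAULT_ALKALINE_PKA = 10.7
DEFAULT_ACID_PKA = 1.5

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class ScaffoldSpec:
    """Scaffold geometry: length, functional-site map, and master seed."""

    length: int = 250
    site_map: Mapping[str, int] = field(default_factory=lambda: dict(BR_SITE_MAP))
    seed: int = 0

    def __post_init__(self):
        positions = list(self.site_map.values())
        if len(set(positions)) != len(positions):
            raise ValidationError("scaffold site positions must be distinct")
        if any(not (1 <= p <= self.length) for p in positions):
            raise ValidationError("scaffold site positions must lie in [1, length]")
        unknown = set(self.site_map) - set(ROLES)
        if unknown:
            raise ValidationError(f"unknown scaffold roles: {sorted(unknown)}")


@dataclass(frozen=True)
class CladeTemplate:
    """Recipe for one clade of planted homologs.

    ``divergence`` is the expected substitutions per site between a member
    and its clade founder. ``habitat_weights`` is a categorical distribution
    over marine/freshwater/saline/NA; the cyanorhodopsin-like default puts
    zero mass on marine (a generator default, not a claim about real
    genomes). ``"decoy"`` templates spawn homologs with the Schiff lysine
    ablated — the second negative class besides unrelated random proteins.
    """

    clade_label: str
    motif_triplet: str
    divergence: float = 0.1
    habitat_weights: Mapping[str, float] | None = None

    def __post_init__(self):
        if not (0.0 <= self.divergence <= 0.6):
            raise ValidationError("divergence must be in [0, 0.6]")
        if len(self.motif_triplet) != 3 or any(
            c not in AMINO_ACIDS for c in self.motif_triplet
        ):
            raise ValidationError("motif_triplet must be 3 standard residues")
        if self.habitat_weights is not None:
            if set(self.habitat_weights) - set(HABITATS):
                raise ValidationError("habitat_weights keys must be known habitats")
            total = sum(self.habitat_weights.values())
            if not np.isclose(total, 1.0):
                raise ValidationError("habitat_weights must sum to 1")

    def resolved_habitat_weights(self) -> dict[str, float]:
        if self.habitat_weights is not None:
            return {h: self.habitat_weights.get(h, 0.0) for h in HABITATS}
        if self.clade_label in ("CyR", "CyHR"):
            return {"marine": 0.0, "freshwater": 0.7, "saline": 0.2, "NA": 0.1}
        return {"marine": 0.4, "freshwater": 0.4, "saline": 0.1, "NA": 0.1}


#: a realistic default panel: helix-C motifs by functional class
#: (outward H+ pumps DTE/DTD, Na+ pump NDQ, inward H+ pump with
#: non-carboxylic donor, Cl- pump TSD)
DEFAULT_TEMPLATES: tuple[CladeTemplate, ...] = (
    CladeTemplate("XLR", "DTE"),
    CladeTemplate("NaR", "NDQ"),
    CladeTemplate("XeR", "DTS"),
    CladeTemplate("CyHR", "TSD"),
    CladeTemplate("CyR", "DTD"),
)


@dataclass(frozen=True)
class SyntheticGenomeSet:
    """Generated genomes, their proteomes, references, and the truth table."""

    genomes: tuple[GenomeRecord, ...]
    proteomes: Mapping[str, tuple[FastaRecord, ...]]
    references: tuple[FastaRecord, ...]
    refmaps: Mapping[str, ReferenceMap]
    truth: pd.DataFrame  # protein_id, genome_id, is_rhodopsin, clade_label, motif_triplet


# ---------------------------------------------------------------------------
# sequence machinery


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_AA, size=length)


def _mutate(
    seq: np.ndarray,
    divergence: float,
    protected: frozenset[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Substitution-only mutation: each unprotected site flips with
    probability ``divergence`` to a uniformly drawn different residue."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < divergence)[0]
    for i in hits:
        if int(i) + 1 in protected:  # protected positions are 1-based
            continue
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def _plant_sites(seq: np.ndarray, template: CladeTemplate, site_map: Mapping[str, int]) -> np.ndarray:
    out = seq.copy()
    triplet = template.motif_triplet
    planted = {
        "acceptor": triplet[0],
        "hbond_partner": triplet[1],
        "donor": triplet[2],
        "counterion": "D",
        "release1": "E",
        "release2": "E",
        "schiff_lysine": "A" if template.clade_label == "decoy" else "K",
    }
    for role, residue in planted.items():
        if role in site_map:
            out[site_map[role] - 1] = residue
    return out


def _insert_loop(
    seq: np.ndarray,
    site_map: Mapping[str, int],
    rng: np.random.Generator,
    max_len: int = 5,
    margin: int = 10,
) -> np.ndarray:
    """Insert one short loop at a position at least ``margin`` residues from
    every mapped site (the indel-stress path)."""
    sites = np.array(sorted(site_map.values()))
    candidates = [
        p
        for p in range(1, seq.size)
        if np.min(np.abs(sites - p)) > margin
    ]
    if not candidates:
        return seq
    pos = int(rng.choice(candidates))
    loop = _random_sequence(rng, int(rng.integers(1, max_len + 1)))
    return np.concatenate([seq[:pos], loop, seq[pos:]])


def _scaffold_and_founders(
    spec: ScaffoldSpec, templates: Sequence[CladeTemplate], clade_separation: float = 0.5
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Deterministic scaffold + one founder per template from the spec seed.

    Shared by the reference and genome generators so panels and planted genes
    descend from the same founders.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(1 + len(templates))
    scaffold = _random_sequence(np.random.default_rng(streams[0]), spec.length)
    protected = frozenset(spec.site_map.values())
    founders = []
    for template, stream in zip(templates, streams[1:]):
        rng = np.random.default_rng(stream)
        founder = _mutate(scaffold, clade_separation, protected, rng)
        founders.append(_plant_sites(founder, template, spec.site_map))
    return scaffold, founders


# ---------------------------------------------------------------------------
# generators


def gen_scaffold_refs(
    spec: ScaffoldSpec,
    templates: Sequence[CladeTemplate],
    n_refs_per_clade: int,
    clade_separation: float = 0.5,
) -> tuple[list[FastaRecord], dict[str, ReferenceMap], pd.DataFrame]:
    """Reference panel: ``n_refs_per_clade`` members per clade template.

    Each reference carries its template's motif triplet (and Lys at the
    Schiff site) at the mapped scaffold positions; members of a clade are
    mutants of a common founder and so are closer to each other than to
    other clades at default divergences. Returns the records, a per-reference
    site map (scaffold numbering), and the truth table.
    """
    if n_refs_per_clade < 1:
        raise ValidationError("n_refs_per_clade must be >= 1")
    labels = [t.clade_label for t in templates]
    if len(set(labels)) != len(labels):
        raise ValidationError("templates must have distinct clade labels")
    if not templates:
        raise ValidationError("template list is empty")

    _, founders = _scaffold_and_founders(spec, templates, clade_separation)
    member_streams = np.random.SeedSequence(spec.seed).spawn(1 + len(templates))[1:]
    protected = frozenset(spec.site_map.values())

    records: list[FastaRecord] = []
    refmaps: dict[str, ReferenceMap] = {}
    truth_rows = []
    for template, founder, stream in zip(templates, founders, member_streams):
        rng = np.random.default_rng(stream.spawn(1)[0])
        for i in range(n_refs_per_clade):
            member = _mutate(founder, template.divergence, protected, rng)
            rid = f"{template.clade_label}_ref{i:02d}"
            records.append(
                FastaRecord(rid, "".join(member), f"synthetic {template.clade_label} reference")
            )
            refmaps[rid] = ReferenceMap(
                reference_id=rid, positions=dict(spec.site_map), numbering_label="scaffold"
            )
            truth_rows.append(
                {
                    "protein_id": rid,
                    "genome_id": "",
                    "is_rhodopsin": template.clade_label != "decoy",
                    "clade_label": template.clade_label,
                    "motif_triplet": template.motif_triplet,
                }
            )
    return records, refmaps, pd.DataFrame(truth_rows)


def gen_genome_set(
    templates: Sequence[CladeTemplate],
    n_genomes: int,
    genes_per_genome: int | Sequence[int],
    decoys_per_genome: int,
    seed: int,
    spec: ScaffoldSpec = ScaffoldSpec(),
    clade_separation: float = 0.5,
    indel_stress: bool = False,
    diox1_rate: float = 152 / 154,
    n_refs_per_clade: int = 3,
) -> SyntheticGenomeSet:
    """Genomes with planted rhodopsin genes, random decoys, and metadata.

    Habitat labels are drawn from the genome's template habitat weights;
    decoys are scaffold-length random sequences with the Schiff site ablated
    (unrelated to the scaffold). The truth table covers every emitted
    protein exactly once.
    """
    if not templates:
        raise ValidationError("template list is empty")
    if n_genomes < 1:
        raise ValidationError("n_genomes must be >= 1")
    if isinstance(genes_per_genome, (int, np.integer)):
        gene_counts = [int(genes_per_genome)] * n_genomes
    else:
        gene_counts = [int(x) for x in genes_per_genome]
        if len(gene_counts) != n_genomes:
            raise ValidationError("genes_per_genome length must equal n_genomes")

    _, founders = _scaffold_and_founders(spec, templates, clade_separation)
    protected = frozenset(spec.site_map.values())
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    references, refmaps, _ = gen_scaffold_refs(
        spec, templates, n_refs_per_clade=n_refs_per_clade, clade_separation=clade_separation
    )

    genomes: list[GenomeRecord] = []
    proteomes: dict[str, tuple[FastaRecord, ...]] = {}
    truth_rows = []
    for g in range(n_genomes):
        gid = f"genome{g:03d}"
        t_genome = int(rng.integers(0, len(templates)))
        weights = templates[t_genome].resolved_habitat_weights()
        habitat = str(rng.choice(HABITATS, p=[weights[h] for h in HABITATS]))
        subclade = str(rng.choice(["B", "D", "E"]))
        proteins: list[FastaRecord] = []
        genes: list[tuple[str, str]] = []
        for j in range(gene_counts[g]):
            ti = t_genome if len(templates) == 1 else int(rng.integers(0, len(templates)))
            template = templates[ti]
            member = _mutate(founders[ti], template.divergence, protected, rng)
            if indel_stress and rng.random() < 0.5:
                member = _insert_loop(member, spec.site_map, rng)
            pid = f"{gid}_rh{j}"
            proteins.append(FastaRecord(pid, "".join(member), f"planted {template.clade_label}"))
            genes.append((pid, template.clade_label))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "genome_id": gid,
                    "is_rhodopsin": template.clade_label != "decoy",
                    "clade_label": template.clade_label,
                    "motif_triplet": template.motif_triplet,
                }
            )
        for j in range(decoys_per_genome):
            decoy = _random_sequence(rng, spec.length)
            sp = spec.site_map.get("schiff_lysine")
            if sp is not None and decoy[sp - 1] == "K":
                decoy[sp - 1] = "A"
            pid = f"{gid}_decoy{j}"
            proteins.append(FastaRecord(pid, "".join(decoy), "random decoy"))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "genome_id": gid,
                    "is_rhodopsin": False,
                    "clade_label": "none",
                    "motif_triplet": "",
                }
            )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                subclade=subclade,
                habitat=habitat,
                diox1_present=bool(rng.random() < diox1_rate),
                rhodopsins=tuple((pid, c) for pid, c in genes if c != "decoy"),
            )
        )
        proteomes[gid] = tuple(proteins)

    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "genome_id", "is_rhodopsin", "clade_label", "motif_triplet"],
    )
    if truth["protein_id"].duplicated().any():
        raise AssertionError("truth table must cover each protein exactly once")
    return SyntheticGenomeSet(
        genomes=tuple(genomes),
        proteomes=proteomes,
        references=tuple(references),
        refmaps=refmaps,
        truth=truth,
    )


def gen_flash_dataset(
    model: PhotocycleModel,
    noise_sigma: float,
    seed: int,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    times: np.ndarray = DEFAULT_TIMES,
) -> FlashDataset:
    """Flash-photolysis matrix: forward model plus i.i.d. Gaussian noise."""
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    clean = synth_difference_spectra(model, wavelengths, times)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noisy = clean + rng.normal(0.0, noise_sigma, clean.shape) if noise_sigma > 0 else clean
    return FlashDataset(
        wavelengths=np.asarray(wavelengths, dtype=float),
        times=np.asarray(times, dtype=float),
        delta_a=noisy,
        noise_sigma=noise_sigma,
    )


#: species bands for the two titration sides (protonated, deprotonated):
#: the alkaline transition deprotonates the Schiff base and blue-shifts the
#: visible band toward the M-like 410 nm; the acid transition protonates the
#: acceptor and red-shifts the ground band. A pH-independent protein UV band
#: sits at 280 nm.
_TITRATION_BANDS = {
    "alkaline": (SpectralBand(550.0, 40.0, 1.0), SpectralBand(410.0, 34.0, 0.85)),
    "acid": (SpectralBand(575.0, 42.0, 1.0), SpectralBand(550.0, 40.0, 0.95)),
}
_UV_BAND = SpectralBand(280.0, 18.0, 1.5)

DEFAULT_TITRATION_WAVELENGTHS = np.arange(250.0, 751.0, 5.0)


def gen_titration_dataset(
    pka_true: float,
    acid_side: bool,
    ph_grid: Sequence[float],
    noise_sigma: float,
    seed: int,
    wavelengths: np.ndarray = DEFAULT_TITRATION_WAVELENGTHS,
) -> TitrationDataset:
    """pH-titration series with two-state Henderson-Hasselbalch structure.

    Each spectrum mixes the protonated and deprotonated species bands with
    weights (1 - occupancy, occupancy) at that pH (single pKa, Hill slope 1),
    plus Gaussian noise.
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size < 4:
        raise ValidationError("need at least 4 pH points (fit would be under-determined)")
    if np.any(np.diff(ph) <= 0):
        raise ValidationError("ph_grid must be strictly increasing")
    if np.any((ph < 0) | (ph > 14)):
        raise ValidationError("ph_grid must lie within [0, 14]")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")

    side = "acid" if acid_side else "alkaline"
    prot, deprot = _TITRATION_BANDS[side]
    wl = np.asarray(wavelengths, dtype=float)
    occ = hh_occupancy(ph, pka_true)  # fraction deprotonated
    A = (
        np.outer(prot(wl), 1.0 - occ)
        + np.outer(deprot(wl), occ)
        + _UV_BAND(wl)[:, None]
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        A = A + rng.normal(0.0, noise_sigma, A.shape)
    return TitrationDataset(
        ph=ph, wavelengths=wl, absorbance=A, side=side, noise_sigma=noise_sigma
    )


# ---------------------------------------------------------------------------
# survey-shaped fixture


def survey_records_fixture() -> list[GenomeRecord]:
    """A deterministic 154-genome record set matching the survey's marginals.

    Reconstructed from the survey's stated totals: 56 rhodopsin genes
    (XLR 3, NaR 1, XeR 15, CyHR 24, CyR 13) in 42 possessing genomes
    (2 marine, 29 freshwater, 9 saline, 2 NA) out of 154, with diox1 in
    152/154. Per-subclade placement is synthetic plumbing — only the Total
    row reflects the survey.
    """
    gene_labels = ["XLR"] * 3 + ["NaR"] + ["XeR"] * 15 + ["CyHR"] * 24 + ["CyR"] * 13
    habitats = ["marine"] * 2 + ["freshwater"] * 29 + ["saline"] * 9 + ["NA"] * 2
    subclades_possessing = ["B"] * 20 + ["D"] * 19 + ["E"] * 2 + ["NA"]
    records: list[GenomeRecord] = []
    gi = 0
    for g in range(42):
        n_genes = 2 if g < 14 else 1  # 14*2 + 28*1 = 56
        genes = tuple(
            (f"fixture_g{g:03d}_rh{j}", gene_labels[gi + j]) for j in range(n_genes)
        )
        gi += n_genes
        records.append(
            GenomeRecord(
                genome_id=f"fixture_g{g:03d}",
                subclade=subclades_possessing[g],
                habitat=habitats[g],
                diox1_present=True,
                rhodopsins=genes,
            )
        )
    assert gi == 56
    empty_subclades = ["A"] * 13 + ["C"] * 36 + ["F"] * 4 + ["G"] * 3 + ["B"] * 8 + [
        "D"
    ] * 1 + ["E"] * 13 + ["NA"] * 34
    assert len(empty_subclades) == 112
    for g, sub in enumerate(empty_subclades):
        records.append(
            GenomeRecord(
                genome_id=f"fixture_e{g:03d}",
                subclade=sub,
                habitat="NA",
                diox1_present=g < 110,  # 2 of 154 lack diox1
                rhodopsins=(),
            )
        )
    return records
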