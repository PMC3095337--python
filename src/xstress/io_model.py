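"""Domain types and file formats shared by every pipeline stage.

The pipeline compares two species' expression compendia (species "A" and
"B", e.g. rice and Arabidopsis) at the level of detection calls,
differential expression, ortholog groups, functional annotation and
promoter sequence.  All tabular interchange is TSV; sequences are FASTA.

Conventions
-----------
* Gene identifiers are opaque strings, unique within a species.  No
  TIGR/AGI/probeset syntax is enforced; any probeset-to-gene aliasing is
  resolved upstream of these readers.
* Expression matrices hold strictly positive, linear-scale normalized
  intensities; log2 is taken internally by downstream stages, so both
  MAS5-style and GC-RMA-style inputs work.
* Replicate columns are named ``<sample_id>.<rep>``; a separate
  detection-p matrix of identical shape holds the per-replicate
  detection p-values in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("xstress")

VALID_BASES = frozenset("ACGTN")


class XstressError(Exception):
    """Base class for package errors."""


class FormatError(XstressError):
    """A file does not conform to its documented dialect."""


class ValidationError(XstressError):
    """Parsed data violates a domain invariant."""


class ConfigError(XstressError):
    """A configuration value is out of range or infeasible."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene functional annotation."""

    funcat: list[str] = field(default_factory=list)
    tf_family: str | None = None
    lineage_specific: bool = False


@dataclass
class GeneUniverse:
    """Two species' gene catalogs plus functional annotation.

    ``annotations`` maps gene id -> :class:`GeneAnnotation`.  A gene with
    a ``tf_family`` label is implicitly a member of the "all TFs"
    denominator set used by family-level enrichment.
    """

    species_a_ids: set[str]
    species_b_ids: set[str]
    annotations: dict[str, GeneAnnotation] = field(default_factory=dict)

    def validate(self) -> None:
        overlap = self.species_a_ids & self.species_b_ids
        if overlap:
            raise ValidationError(
                f"{len(overlap)} gene ids occur in both species (e.g. "
                f"{sorted(overlap)[:3]})"
            )
        all_ids = self.species_a_ids | self.species_b_ids
        orphans = [g for g in self.annotations if g not in all_ids]
        if orphans:
            raise ValidationError(
                f"{len(orphans)} annotated genes missing from both id sets "
                f"(e.g. {orphans[:3]})"
            )

    def species_of(self, gene: str) -> str:
        if gene in self.species_a_ids:
            return "A"
        if gene in self.species_b_ids:
            return "B"
        raise KeyError(gene)

    def tf_genes(self, species: str) -> set[str]:
        """All genes of a species carrying a TF-family label."""
        ids = self.species_a_ids if species == "A" else self.species_b_ids
        return {g for g in ids
                if self.annotations.get(g, _NO_ANNOT).tf_family is not None}


_NO_ANNOT = GeneAnnotation()


@dataclass
class SampleMeta:
    """Metadata for one biological sample (a set of replicate arrays)."""

    sample_id: str
    organ: str | None = None
    stage: str | None = None
    stress: str | None = None
    time_point_h: float | None = None
    control_sample_id: str | None = None
    replicate_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.time_point_h is not None and self.time_point_h < 0:
            raise ValidationError(
                f"sample {self.sample_id}: time_point_h must be >= 0"
            )
        if (self.stress is not None and self.stress != "control"
                and self.control_sample_id is None):
            raise ValidationError(
                f"stress sample {self.sample_id} has no paired control"
            )


@dataclass
class ExpressionStudy:
    """A genes x replicates intensity matrix with detection p-values.

    ``intensity`` and ``detection_p`` are DataFrames indexed by gene with
    identical ``<sample_id>.<rep>`` columns.  ``samples`` carries the
    grouping of replicate columns into biological samples.
    """

    genes: list[str]
    samples: list[SampleMeta]
    intensity: pd.DataFrame
    detection_p: pd.DataFrame

    def validate(self) -> None:
        if list(self.intensity.index) != self.genes:
            raise ValidationError("intensity rows do not match gene list")
        if list(self.detection_p.index) != self.genes:
            raise ValidationError("detection_p rows do not match gene list")
        if list(self.intensity.columns) != list(self.detection_p.columns):
            bad = set(self.intensity.columns) ^ set(self.detection_p.columns)
            raise FormatError(
                f"intensity/detection column mismatch: {sorted(bad)[:5]}"
            )
        claimed = [r for s in self.samples for r in s.replicate_ids]
        if sorted(claimed) != sorted(self.intensity.columns):
            bad = set(claimed) ^ set(self.intensity.columns)
            raise FormatError(
                f"sample metadata does not cover matrix columns: "
                f"{sorted(bad)[:5]}"
            )
        dp = self.detection_p.to_numpy()
        if np.isnan(dp).any() or (dp < 0).any() or (dp > 1).any():
            raise ValidationError("detection p-values must lie in [0, 1]")
        if (self.intensity.to_numpy() <= 0).any():
            raise ValidationError(
                "intensities must be strictly positive linear-scale values"
            )
        for s in self.samples:
            s.validate()
            if len(s.replicate_ids) < 2:
                logger.warning(
                    "sample %s has only %d replicate(s); presence calls "
                    "will be low-powered", s.sample_id, len(s.replicate_ids)
                )

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def replicate_columns(self, sample_id: str) -> list[str]:
        return self.sample(sample_id).replicate_ids

    def log2_intensity(self, sample_id: str) -> np.ndarray:
        """log2 intensities (genes x replicates) for one sample."""
        cols = self.replicate_columns(sample_id)
        return np.log2(self.intensity[cols].to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and self.intensity.columns.equals(other.intensity.columns)
            and np.allclose(self.intensity.to_numpy(),
                            other.intensity.to_numpy())
            and np.allclose(self.detection_p.to_numpy(),
                            other.detection_p.to_numpy())
        )


@dataclass
class OrthologGroupMap:
    """Two-species ortholog groups (InParanoid-style).

    Each group holds at least one gene from species A and one from
    species B.  A gene belongs to at most one group; duplicates in the
    input are resolved by keeping the first occurrence.
    """

    groups: list[tuple[list[str], list[str]]]
    _index: dict[str, tuple[int, str]] = field(default_factory=dict,
                                               repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            for gid, (a_members, b_members) in enumerate(self.groups):
                if not a_members or not b_members:
                    raise ValidationError(
                        f"group {gid} lacks members from one species"
                    )
                for g in a_members:
                    self._index[g] = (gid, "A")
                for g in b_members:
                    self._index[g] = (gid, "B")

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, gene: str) -> int | None:
        hit = self._index.get(gene)
        return None if hit is None else hit[0]

    def partners(self, gene: str) -> list[str]:
        """Genes of the *other* species sharing this gene's group."""
        hit = self._index.get(gene)
        if hit is None:
            return []
        gid, side = hit
        a_members, b_members = self.groups[gid]
        return list(b_members if side == "A" else a_members)

    def genes(self, species: str) -> set[str]:
        side = 0 if species == "A" else 1
        return {g for grp in self.groups for g in grp[side]}

    def validate_against(self, universe: GeneUniverse) -> None:
        bad = [g for g in self.genes("A") if g not in universe.species_a_ids]
        bad += [g for g in self.genes("B") if g not in universe.species_b_ids]
        if bad:
            raise ValidationError(
                f"{len(bad)} ortholog-group members unknown to the gene "
                f"universe (e.g. {bad[:3]})"
            )


@dataclass
class DEGRecord:
    """Differential-expression result for one gene in one contrast."""

    gene: str
    contrast: str
    log2fc: float
    p_value: float
    ppde: float
    direction: str  # up | down | unchanged


DEG_COLUMNS = ["gene", "contrast", "log2fc", "p_value", "ppde", "direction"]


def deg_table(records: Iterable[DEGRecord]) -> pd.DataFrame:
    """Assemble DEGRecords into the canonical DEG table."""
    df = pd.DataFrame(
        [(r.gene, r.contrast, r.log2fc, r.p_value, r.ppde, r.direction)
         for r in records],
        columns=DEG_COLUMNS,
    )
    return df


@dataclass
class EnrichmentResult:
    """Over/under-representation of one category in a gene subset."""

    category: str
    k_subset: int
    n_subset: int
    k_genome: int
    n_genome: int
    z: float
    p_value: float
    flag: str  # over | under | none
    method: str = "two_prop_z"

    @property
    def p_hat_subset(self) -> float:
        return self.k_subset / self.n_subset if self.n_subset else float("nan")

    @property
    def p_hat_genome(self) -> float:
        return self.k_genome / self.n_genome if self.n_genome else float("nan")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _split_replicate(col: str) -> str:
    """Sample id of a ``<sample_id>.<rep>`` replicate column."""
    if "." not in col:
        raise FormatError(
            f"replicate column {col!r} is not of the form <sample>.<rep>"
        )
    return col.rsplit(".", 1)[0]


def read_expression_study(intensity_path, detection_path,
                          meta_path) -> ExpressionStudy:
    """Load an expression study from its three TSV files.

    The intensity and detection files share genes in rows and replicate
    columns named ``<sample_id>.<rep>``; the metadata file has columns
    sample_id, organ, stage, stress, time_point_h, control_sample_id.
    """
    intensity = pd.read_csv(intensity_path, sep="\t", index_col=0)
    detection = pd.read_csv(detection_path, sep="\t", index_col=0)
    if list(intensity.columns) != list(detection.columns):
        bad = set(intensity.columns) ^ set(detection.columns)
        raise FormatError(
            f"intensity/detection replicate columns differ: {sorted(bad)[:5]}"
        )
    if list(intensity.index) != list(detection.index):
        raise FormatError("intensity/detection gene rows differ")

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id"}
    if not required <= set(meta.columns):
        raise FormatError(f"metadata lacks columns {required - set(meta.columns)}")

    by_sample: dict[str, list[str]] = {}
    for col in intensity.columns:
        by_sample.setdefault(_split_replicate(col), []).append(col)

    samples = []
    for _, row in meta.iterrows():
        sid = str(row["sample_id"])
        if sid not in by_sample:
            raise FormatError(
                f"metadata sample {sid} has no replicate columns in the matrix"
            )

        def _opt(key):
            val = row.get(key)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                return None
            return val

        tp = _opt("time_point_h")
        samples.append(SampleMeta(
            sample_id=sid,
            organ=_opt("organ"),
            stage=_opt("stage"),
            stress=_opt("stress"),
            time_point_h=float(tp) if tp is not None else None,
            control_sample_id=_opt("control_sample_id"),
            replicate_ids=by_sample[sid],
        ))
    covered = {c for s in samples for c in s.replicate_ids}
    extra = [c for c in intensity.columns if c not in covered]
    if extra:
        raise FormatError(
            f"replicate columns with no metadata sample: {extra[:5]}"
        )

    study = ExpressionStudy(
        genes=list(intensity.index),
        samples=samples,
        intensity=intensity,
        detection_p=detection,
    )
    study.validate()
    return study


def write_expression_study(study: ExpressionStudy, intensity_path,
                           detection_path, meta_path) -> None:
    study.intensity.to_csv(intensity_path, sep="\t", index_label="gene_id")
    study.detection_p.to_csv(detection_path, sep="\t", index_label="gene_id")
    rows = []
    for s in study.samples:
        rows.append({
            "sample_id": s.sample_id,
            "organ": s.organ,
            "stage": s.stage,
            "stress": s.stress,
            "time_point_h": s.time_point_h,
            "control_sample_id": s.control_sample_id,
        })
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_ortholog_groups(path) -> OrthologGroupMap:
    """Parse a two-species ortholog group TSV.

    Columns: group_id, species (A|B), gene_id; header row required.
    Groups with members from a single species define no cross-species
    orthology and are skipped with a warning.  A gene listed in several
    groups keeps its first occurrence (file order), matching the
    main-ortholog uniqueness convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group_id", "species", "gene_id"}
    if not required <= set(df.columns):
        raise FormatError(
            f"ortholog file lacks columns {sorted(required - set(df.columns))}"
        )
    bad_species = set(df["species"]) - {"A", "B"}
    if bad_species:
        raise FormatError(f"unknown species labels: {sorted(bad_species)}")

    seen: set[str] = set()
    groups: list[tuple[list[str], list[str]]] = []
    n_single = n_dup = 0
    for gid, sub in df.groupby("group_id", sort=False):
        a_members, b_members = [], []
        for _, row in sub.iterrows():
            gene = row["gene_id"]
            if gene in seen:
                n_dup += 1
                continue
            seen.add(gene)
            (a_members if row["species"] == "A" else b_members).append(gene)
        if a_members and b_members:
            groups.append((a_members, b_members))
        else:
            n_single += 1
    if n_single:
        logger.warning(
            "%d ortholog group(s) had members from one species only and "
            "were skipped", n_single
        )
    if n_dup:
        logger.warning(
            "%d gene occurrence(s) in later groups dropped (gene already "
            "assigned to an earlier group)", n_dup
        )
    return OrthologGroupMap(groups=groups)


def write_ortholog_groups(orthos: OrthologGroupMap, path) -> None:
    rows = []
    for gid, (a_members, b_members) in enumerate(orthos.groups):
        for g in a_members:
            rows.append((f"g{gid}", "A", g))
        for g in b_members:
            rows.append((f"g{gid}", "B", g))
    pd.DataFrame(rows, columns=["group_id", "species", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta_set(path) -> dict[str, str]:
    """Read a FASTA file into a gene id -> uppercase sequence map.

    Sequences must be over {A, C, G, T, N} after uppercasing (N is the
    only ambiguity code retained; other IUPAC letters are rejected so
    k-mer semantics stay unambiguous).  Duplicate ids are an error.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FormatError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {record.id!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )
        out[record.id] = seq
    return out


def write_fasta_set(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="")
               for gene, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path) -> dict[str, GeneAnnotation]:
    """Read the annotation TSV: gene_id, funcat (';'-separated),
    tf_family, lineage_specific (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "funcat", "tf_family", "lineage_specific"}
    if not required <= set(df.columns):
        raise FormatError(
            f"annotation file lacks columns {sorted(required - set(df.columns))}"
        )
    out: dict[str, GeneAnnotation] = {}
    for _, row in df.iterrows():
        funcat = [c for c in row["funcat"].split(";") if c]
        out[row["gene_id"]] = GeneAnnotation(
            funcat=funcat,
            tf_family=row["tf_family"] or None,
            lineage_specific=row["lineage_specific"] in ("1", "True", "true"),
        )
    return out


def write_annotations(annotations: Mapping[str, GeneAnnotation], path) -> None:
    rows = []
    for gene, ann in annotations.items():
        rows.append({
            "gene_id": gene,
            "funcat": ";".join(ann.funcat),
            "tf_family": ann.tf_family or "",
            "lineage_specific": int(ann.lineage_specific),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
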