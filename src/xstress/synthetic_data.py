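"""Two-species synthetic datasets with planted, recoverable structure.

The generator emulates the statistical shape of a two-species microarray
compendium — two gene universes with a configurable orthologous
fraction per species, replicate detection-call structure, log-normal
intensities with planted differential expression under several
"stresses", planted cross-species response classes
(common/opposite/one-species-only), planted functional-category
enrichment, and i.i.d.-background promoter/3'UTR sequences with planted
motifs at controlled fold enrichment — together with a truth object so
recovery can be tested end to end.

Default study conditions: four stresses (drought, salt, cold, heat)
with one control/treated sample pair each and 3 replicates; 37% of
species-A genes and 61% of species-B genes orthologous (the asymmetry
of a large genome against a compact one); a breadth mix of 16% always /
26% never / 5% specific / 53% nonspecific expressed genes; a planted
log2 effect of 2.0 against a within-replicate SD of 0.25; detection
p-values drawn from Uniform(0, 0.04) for present and Uniform(0.06, 1)
for absent replicates so the p < 0.05 presence threshold is
unambiguous.

Determinism: every output artifact draws from its own labeled RNG
substream derived from the master seed, so identical configs give
byte-identical outputs and adding an artifact never perturbs others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_model import (ConfigError, ExpressionStudy, GeneAnnotation,
                       GeneUniverse, OrthologGroupMap, SampleMeta,
                       write_annotations, write_expression_study,
                       write_fasta_set, write_ortholog_groups)
from .motif_scan import UtrMotifCatalog

logger = logging.getLogger("xstress")

STRESS_NAMES = ("drought", "salt", "cold", "heat")

FUNCATS = (
    "metabolism", "energy", "transcription", "translation",
    "protein fate", "cellular transport", "signal transduction",
    "stress response", "development", "cell wall", "redox",
    "unclassified",
)
_FUNCAT_WEIGHTS = (0.18, 0.06, 0.10, 0.05, 0.08, 0.09, 0.07,
                   0.06, 0.05, 0.04, 0.03, 0.19)

TF_FAMILIES = ("AP2", "NAC", "WRKY", "bZIP", "HSF", "MYB", "GATA", "ARF")
_TF_WEIGHTS = (0.20, 0.15, 0.15, 0.13, 0.05, 0.17, 0.07, 0.08)

# editable defaults for the 3'UTR stability catalog; the synthetic
# stabilising entries are placeholders for literature motifs
DEFAULT_UTR_CATALOG = [
    ("DST_core", "destabilising", "ATAGAT"),
    ("ARE_pentamer", "destabilising", "ATTTA"),
    ("synthetic_stab_1", "stabilising", "GTTACCGA"),
    ("synthetic_stab_2", "stabilising", "CCTAGCTT"),
]


def _check_mix(name: str, mix: dict[str, float], keys: tuple[str, ...]):
    if set(mix) != set(keys):
        raise ConfigError(f"{name} must have keys {keys}, got {sorted(mix)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} proportions sum to {total}, not 1")
    if any(v < 0 for v in mix.values()):
        raise ConfigError(f"{name} proportions must be non-negative")


@dataclass
class SimConfig:
    """Full parameterization of a synthetic two-species dataset."""

    seed: int = 0
    n_genes_a: int = 3000
    n_genes_b: int = 2000
    frac_orthologous_a: float = 0.37
    frac_orthologous_b: float = 0.61
    frac_one_to_many: float = 0.10
    n_stresses: int = 4
    n_replicates: int = 3
    frac_de_per_stress: float = 0.15
    log2fc_effect: float = 2.0
    sigma_within: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    response_class_mix: dict[str, float] = field(default_factory=lambda: {
        "common": 0.25, "opposite": 0.10, "a_only": 0.35, "b_only": 0.30,
    })
    presence_class_mix: dict[str, float] = field(default_factory=lambda: {
        "always": 0.16, "never": 0.26, "specific": 0.05, "nonspecific": 0.53,
    })
    core_counts: dict[str, int] = field(default_factory=lambda: {
        "common_up": 9, "common_down": 3,
        "opposite_a_up": 7, "opposite_a_down": 3,
        "a_only_up": 20, "a_only_down": 25,
        "b_only_up": 12, "b_only_down": 8,
    })
    promoter_length: int = 1000
    utr_length: int = 300
    gc_content: float = 0.42
    kmer_k: int = 6
    planted_motifs: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("CACGTG", "a_drought_up", 2.0)]
    )
    planted_utr_motifs: list[tuple[str, str, str, float]] = field(
        default_factory=lambda: [
            ("ATAGAT", "destabilising", "a_drought_down", 0.5),
        ]
    )
    funcat_enrichment: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("stress response", "a_drought_up", 3.0)]
    )
    tf_frac: float = 0.06
    lineage_frac_a: float = 0.014
    lineage_frac_b: float = 0.004
    detection_p_present: tuple[float, float] = (0.0, 0.04)
    detection_p_absent: tuple[float, float] = (0.06, 1.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("frac_orthologous_a", "frac_orthologous_b",
                     "frac_one_to_many", "frac_de_per_stress", "gc_content",
                     "tf_frac", "lineage_frac_a", "lineage_frac_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_genes_a < 1 or self.n_genes_b < 1:
            raise ConfigError("both species need at least one gene")
        if (self.frac_orthologous_a > 0) != (self.frac_orthologous_b > 0):
            raise ConfigError(
                "orthologous fractions must be both zero or both positive: "
                "one species cannot have orthologs without the other"
            )
        if self.n_stresses < 1 or self.n_replicates < 1:
            raise ConfigError("n_stresses and n_replicates must be >= 1")
        if self.log2fc_effect <= 0:
            raise ConfigError("log2fc_effect must be positive")
        if self.sigma_within < 0:
            raise ConfigError("sigma_within must be >= 0")
        _check_mix("response_class_mix", self.response_class_mix,
                   ("common", "opposite", "a_only", "b_only"))
        _check_mix("presence_class_mix", self.presence_class_mix,
                   ("always", "never", "specific", "nonspecific"))
        for motif, label, fold in self.planted_motifs:
            if len(motif) != self.kmer_k:
                raise ConfigError(
                    f"planted motif {motif!r} is not length k={self.kmer_k}"
                )
            if fold <= 0:
                raise ConfigError(f"motif fold {fold} must be positive")
        lo, hi = self.detection_p_present
        lo2, hi2 = self.detection_p_absent
        if not (0 <= lo < hi <= 1 and 0 <= lo2 < hi2 <= 1):
            raise ConfigError("detection p-model bounds must be ordered "
                              "within [0, 1]")

    @property
    def stresses(self) -> list[str]:
        names = list(STRESS_NAMES)
        while len(names) < self.n_stresses:
            names.append(f"stress{len(names) + 1}")
        return names[:self.n_stresses]

    def rng(self, label: str) -> np.random.Generator:
        """Labeled RNG substream derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(label.encode())])
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        for key in ("planted_motifs", "planted_utr_motifs",
                    "funcat_enrichment"):
            if key in data:
                data[key] = [tuple(item) for item in data[key]]
        for key in ("detection_p_present", "detection_p_absent"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimTruth:
    """Everything the generator planted, for recovery testing."""

    presence_class: dict[str, str]
    presence_samples: dict[str, list[str]]
    de_direction: dict[str, dict[str, str]]   # "a_drought" -> gene -> dir
    expected_class: dict[str, dict[str, str]]  # "a_drought" -> gene -> class
    core: dict[str, list[str]]                 # "a_up", "a_down", ...
    planted_motifs: list[tuple[str, str, float]]
    planted_utr_motifs: list[tuple[str, str, str, float]]
    planted_categories: list[tuple[str, str, float]]
    stresses: list[str]
    samples: dict[str, list[str]]              # species -> sample ids

    def gene_set(self, label: str) -> set[str]:
        """Resolve a planted-set label like ``a_drought_up`` or
        ``b_core_down`` to its gene set."""
        sp, rest = label.split("_", 1)
        if rest.startswith("core_"):
            return set(self.core[f"{sp}_{rest.split('_', 1)[1]}"])
        stress, direction = rest.rsplit("_", 1)
        key = f"{sp}_{stress}"
        return {g for g, d in self.de_direction.get(key, {}).items()
                if d == direction}

    def to_dict(self) -> dict:
        return {
            "presence_class": self.presence_class,
            "presence_samples": self.presence_samples,
            "de_direction": self.de_direction,
            "expected_class": self.expected_class,
            "core": self.core,
            "planted_motifs": [list(m) for m in self.planted_motifs],
            "planted_utr_motifs": [list(m) for m in self.planted_utr_motifs],
            "planted_categories": [list(c) for c in self.planted_categories],
            "stresses": self.stresses,
            "samples": self.samples,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimTruth":
        return cls(
            presence_class=data["presence_class"],
            presence_samples=data["presence_samples"],
            de_direction=data["de_direction"],
            expected_class=data["expected_class"],
            core=data["core"],
            planted_motifs=[tuple(m) for m in data["planted_motifs"]],
            planted_utr_motifs=[tuple(m)
                                for m in data["planted_utr_motifs"]],
            planted_categories=[tuple(c)
                                for c in data["planted_categories"]],
            stresses=data["stresses"],
            samples=data["samples"],
        )


def _sample_ids(config: SimConfig) -> list[str]:
    out = []
    for stress in config.stresses:
        out.append(f"{stress}_ctl")
        out.append(f"{stress}_trt")
    return out


# ---------------------------------------------------------------------------
# Universe, orthology and truth
# ---------------------------------------------------------------------------

def generate_universe(config: SimConfig,
                      ) -> tuple[GeneUniverse, OrthologGroupMap, SimTruth]:
    """Create both gene catalogs, the ortholog map and the full truth.

    Orthology membership is a per-gene Bernoulli draw at each species'
    configured fraction; groups pair one species-A gene with one or more
    species-B genes (or vice versa), the richer side's excess
    concentrated into roughly ``frac_one_to_many`` of the groups.  All
    planted structure — presence classes, per-stress response classes,
    core genes, category enrichment — is decided here; the expression
    and sequence generators only realize it.
    """
    genes_a = [f"A{i:05d}" for i in range(config.n_genes_a)]
    genes_b = [f"B{i:05d}" for i in range(config.n_genes_b)]

    orthos = _make_groups(config, genes_a, genes_b)
    truth = _plant_truth(config, genes_a, genes_b, orthos)
    annotations = _make_annotations(config, genes_a, genes_b, truth)

    universe = GeneUniverse(
        species_a_ids=set(genes_a),
        species_b_ids=set(genes_b),
        annotations=annotations,
    )
    universe.validate()
    orthos.validate_against(universe)
    return universe, orthos, truth


def _make_groups(config: SimConfig, genes_a: list[str],
                 genes_b: list[str]) -> OrthologGroupMap:
    rng = config.rng("universe")
    in_a = rng.random(len(genes_a)) < config.frac_orthologous_a
    in_b = rng.random(len(genes_b)) < config.frac_orthologous_b
    ortho_a = [g for g, keep in zip(genes_a, in_a) if keep]
    ortho_b = [g for g, keep in zip(genes_b, in_b) if keep]
    if not ortho_a or not ortho_b:
        if config.frac_orthologous_a > 0 or config.frac_orthologous_b > 0:
            logger.warning("orthologous fraction realized as zero on one "
                           "side; emitting an empty group map")
        return OrthologGroupMap(groups=[])
    rng.shuffle(ortho_a)
    rng.shuffle(ortho_b)
    small, large, a_is_small = (
        (ortho_a, ortho_b, True) if len(ortho_a) <= len(ortho_b)
        else (ortho_b, ortho_a, False)
    )
    n_groups = len(small)
    extra = len(large) - n_groups
    members_large: list[list[str]] = [[g] for g in large[:n_groups]]
    if extra:
        # concentrate the excess into ~frac_one_to_many of the groups
        n_multi = max(1, int(round(config.frac_one_to_many * n_groups)))
        n_multi = min(n_multi, n_groups)
        targets = rng.choice(n_groups, size=n_multi, replace=False)
        for i, gene in enumerate(large[n_groups:]):
            members_large[targets[i % n_multi]].append(gene)
    groups = []
    for small_gene, large_members in zip(small, members_large):
        if a_is_small:
            groups.append(([small_gene], large_members))
        else:
            groups.append((large_members, [small_gene]))
    return OrthologGroupMap(groups=groups)


def _plant_truth(config: SimConfig, genes_a: list[str], genes_b: list[str],
                 orthos: OrthologGroupMap) -> SimTruth:
    rng = config.rng("truth")
    stresses = config.stresses
    sample_ids = _sample_ids(config)
    n_samples = len(sample_ids)

    # --- presence classes first: the configured mix is realized exactly
    # as a multinomial; differential expression is then planted only in
    # genes detectable in the relevant stress samples, so the breadth
    # mix is never distorted by the DE layer.
    presence_class: dict[str, str] = {}
    presence_samples: dict[str, list[str]] = {}
    class_names = ("always", "never", "specific", "nonspecific")
    class_probs = np.array([config.presence_class_mix[c]
                            for c in class_names])
    for genes in (genes_a, genes_b):
        draws = rng.choice(len(class_names), size=len(genes), p=class_probs)
        for gene, cls_idx in zip(genes, draws):
            cls = class_names[cls_idx]
            if cls == "always":
                present = set(sample_ids)
            elif cls == "never":
                present = set()
            elif cls == "specific":
                present = {sample_ids[rng.integers(n_samples)]}
            else:
                if n_samples <= 3:
                    present = set(sample_ids[:2]) or set(sample_ids)
                else:
                    size = int(rng.integers(2, n_samples))  # 2..n-1
                    idx = rng.choice(n_samples, size=size, replace=False)
                    present = {sample_ids[i] for i in idx}
            presence_class[gene] = cls
            presence_samples[gene] = sorted(present)

    def detectable(gene: str, stress: str) -> bool:
        """Present in the control and/or treated sample of the stress
        (the condition for entering that contrast's analysis)."""
        ps = presence_samples[gene]
        return f"{stress}_ctl" in ps or f"{stress}_trt" in ps

    def detectable_all(gene: str) -> bool:
        return all(detectable(gene, s) for s in stresses)

    de_direction: dict[str, dict[str, str]] = {
        f"{sp}_{s}": {} for sp in "ab" for s in stresses
    }
    expected_class: dict[str, dict[str, str]] = {
        f"{sp}_{s}": {} for sp in "ab" for s in stresses
    }
    core: dict[str, list[str]] = {f"{sp}_{d}": [] for sp in "ab"
                                  for d in ("up", "down")}

    def focal_pair(gid: int) -> tuple[str, str]:
        a_members, b_members = orthos.groups[gid]
        return a_members[0], b_members[0]

    nonortho_a = [g for g in genes_a if orthos.group_of(g) is None]
    nonortho_b = [g for g in genes_b if orthos.group_of(g) is None]

    # --- core genes: consistent direction under every stress ------------
    core_pool = [gid for gid in range(len(orthos.groups))
                 if detectable_all(focal_pair(gid)[0])
                 and detectable_all(focal_pair(gid)[1])]
    rng.shuffle(core_pool)
    core_pool_iter = iter(core_pool)
    core_nonortho = {
        "a": iter([g for g in nonortho_a if detectable_all(g)]),
        "b": iter([g for g in nonortho_b if detectable_all(g)]),
    }

    def plant_core(gene: str, sp: str, direction: str, cls_by_stress: str):
        core[f"{sp}_{direction}"].append(gene)
        for s in stresses:
            de_direction[f"{sp}_{s}"][gene] = direction
            expected_class[f"{sp}_{s}"][gene] = cls_by_stress

    def take_core_group() -> int:
        try:
            return next(core_pool_iter)
        except StopIteration:
            raise ConfigError(
                "not enough ortholog groups with both focal genes "
                "detectable under every stress to plant the configured "
                "core counts"
            ) from None

    used_core_groups: set[int] = set()
    for kind, count in config.core_counts.items():
        for _ in range(count):
            if kind in ("common_up", "common_down"):
                direction = kind.split("_")[1]
                gid = take_core_group()
                used_core_groups.add(gid)
                ga, gb = focal_pair(gid)
                plant_core(ga, "a", direction, f"common_{direction}")
                plant_core(gb, "b", direction, f"common_{direction}")
            elif kind in ("opposite_a_up", "opposite_a_down"):
                dir_a = kind.rsplit("_", 1)[1]
                dir_b = "down" if dir_a == "up" else "up"
                gid = take_core_group()
                used_core_groups.add(gid)
                ga, gb = focal_pair(gid)
                plant_core(ga, "a", dir_a, "opposite")
                plant_core(gb, "b", dir_b, "opposite")
            elif kind in ("a_only_up", "a_only_down", "b_only_up",
                          "b_only_down"):
                sp, _, direction = kind.split("_")
                # half from groups (partner unchanged), half non-ortholog
                if rng.random() < 0.5:
                    gid = take_core_group()
                    used_core_groups.add(gid)
                    ga, gb = focal_pair(gid)
                    gene = ga if sp == "a" else gb
                    plant_core(gene, sp, direction, "ortholog_unchanged")
                else:
                    try:
                        gene = next(core_nonortho[sp])
                    except StopIteration:
                        raise ConfigError(
                            "not enough detectable non-orthologous genes "
                            "to plant the configured core counts"
                        ) from None
                    plant_core(gene, sp, direction, "no_ortholog")
            else:
                raise ConfigError(f"unknown core kind {kind!r}")

    # --- per-stress differential expression -----------------------------
    classes = ("common", "opposite", "a_only", "b_only")
    probs = np.array([config.response_class_mix[c] for c in classes])
    for stress in stresses:
        eligible = [gid for gid in range(len(orthos.groups))
                    if gid not in used_core_groups
                    and detectable(focal_pair(gid)[0], stress)
                    and detectable(focal_pair(gid)[1], stress)]
        n_pairs = int(round(config.frac_de_per_stress * len(eligible)))
        if n_pairs:
            chosen = rng.choice(len(eligible), size=n_pairs, replace=False)
            drawn_classes = rng.choice(len(classes), size=n_pairs, p=probs)
            for idx, cls_idx in zip(chosen, drawn_classes):
                gid = eligible[idx]
                cls = classes[cls_idx]
                ga, gb = focal_pair(gid)
                direction = "up" if rng.random() < 0.5 else "down"
                reverse = "down" if direction == "up" else "up"
                key_a, key_b = f"a_{stress}", f"b_{stress}"
                if cls == "common":
                    de_direction[key_a][ga] = direction
                    de_direction[key_b][gb] = direction
                    expected_class[key_a][ga] = f"common_{direction}"
                    expected_class[key_b][gb] = f"common_{direction}"
                elif cls == "opposite":
                    de_direction[key_a][ga] = direction
                    de_direction[key_b][gb] = reverse
                    expected_class[key_a][ga] = "opposite"
                    expected_class[key_b][gb] = "opposite"
                elif cls == "a_only":
                    de_direction[key_a][ga] = direction
                    expected_class[key_a][ga] = "ortholog_unchanged"
                else:
                    de_direction[key_b][gb] = direction
                    expected_class[key_b][gb] = "ortholog_unchanged"
        # non-orthologous DE, independent per stress
        for sp, pool in (("a", nonortho_a), ("b", nonortho_b)):
            key = f"{sp}_{stress}"
            free = [g for g in pool if g not in de_direction[key]
                    and g not in core[f"{sp}_up"]
                    and g not in core[f"{sp}_down"]
                    and detectable(g, stress)]
            n_de = int(round(config.frac_de_per_stress * len(free)))
            if n_de:
                chosen = rng.choice(len(free), size=n_de, replace=False)
                dirs = rng.random(n_de) < 0.5
                for idx, up in zip(chosen, dirs):
                    gene = free[idx]
                    direction = "up" if up else "down"
                    de_direction[key][gene] = direction
                    expected_class[key][gene] = "no_ortholog"

    return SimTruth(
        presence_class=presence_class,
        presence_samples=presence_samples,
        de_direction=de_direction,
        expected_class=expected_class,
        core=core,
        planted_motifs=list(config.planted_motifs),
        planted_utr_motifs=list(config.planted_utr_motifs),
        planted_categories=list(config.funcat_enrichment),
        stresses=list(stresses),
        samples={"a": sample_ids, "b": list(sample_ids)},
    )


def _make_annotations(config: SimConfig, genes_a: list[str],
                      genes_b: list[str],
                      truth: SimTruth) -> dict[str, GeneAnnotation]:
    rng = config.rng("annotations")
    annotations: dict[str, GeneAnnotation] = {}
    weights = np.array(_FUNCAT_WEIGHTS)
    tf_weights = np.array(_TF_WEIGHTS)
    for sp, genes, lineage_frac in (("a", genes_a, config.lineage_frac_a),
                                    ("b", genes_b, config.lineage_frac_b)):
        primary = rng.choice(len(FUNCATS), size=len(genes), p=weights)
        second_mask = rng.random(len(genes)) < 0.25
        secondary = rng.choice(len(FUNCATS), size=len(genes), p=weights)
        is_tf = rng.random(len(genes)) < config.tf_frac
        families = rng.choice(len(TF_FAMILIES), size=len(genes),
                              p=tf_weights)
        lineage = rng.random(len(genes)) < lineage_frac
        for i, gene in enumerate(genes):
            funcat = [FUNCATS[primary[i]]]
            if second_mask[i] and FUNCATS[secondary[i]] != funcat[0]:
                funcat.append(FUNCATS[secondary[i]])
            annotations[gene] = GeneAnnotation(
                funcat=funcat,
                tf_family=TF_FAMILIES[families[i]] if is_tf[i] else None,
                lineage_specific=bool(lineage[i]),
            )
    # planted category enrichment: raise the category's rate in the
    # target set to fold x its background rate
    for category, label, fold in config.funcat_enrichment:
        if category not in FUNCATS:
            raise ConfigError(f"unknown planted category {category!r}")
        base = weights[FUNCATS.index(category)]
        if fold * base > 1.0:
            raise ConfigError(
                f"planted enrichment {category!r} x{fold} exceeds "
                "probability 1"
            )
        add_p = (fold - 1.0) * base / (1.0 - base)
        for gene in sorted(truth.gene_set(label)):
            ann = annotations[gene]
            if category not in ann.funcat and rng.random() < add_p:
                ann.funcat.append(category)
    return annotations


# ---------------------------------------------------------------------------
# Expression realization
# ---------------------------------------------------------------------------

def generate_expression(config: SimConfig, universe: GeneUniverse,
                        truth: SimTruth,
                        species: str = "A") -> ExpressionStudy:
    """Realize one species' intensity and detection-p matrices.

    Replicate log2 intensities are Normal(baseline + effect x planted
    direction, sigma_within); the planted effect applies only in the
    treated sample of the gene's DE stresses.  Detection p-values are
    drawn from the present interval for replicates of samples where the
    truth says the gene is present, and the absent interval otherwise.
    """
    sp = species.lower()
    genes = sorted(universe.species_a_ids if sp == "a"
                   else universe.species_b_ids)
    rng = config.rng(f"expression_{sp}")
    sample_ids = truth.samples[sp]
    n_reps = config.n_replicates
    n_genes = len(genes)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=n_genes)
    present_lookup = {g: set(truth.presence_samples.get(g, []))
                      for g in genes}

    samples: list[SampleMeta] = []
    intensity_cols: dict[str, np.ndarray] = {}
    detection_cols: dict[str, np.ndarray] = {}
    lo_p, hi_p = config.detection_p_present
    lo_a, hi_a = config.detection_p_absent
    for sid in sample_ids:
        stress, kind = sid.rsplit("_", 1)
        meta = SampleMeta(
            sample_id=sid,
            stress=stress if kind == "trt" else "control",
            control_sample_id=f"{stress}_ctl" if kind == "trt" else None,
            replicate_ids=[f"{sid}.{r + 1}" for r in range(n_reps)],
        )
        samples.append(meta)
        shift = np.zeros(n_genes)
        if kind == "trt":
            key = f"{sp}_{stress}"
            for i, gene in enumerate(genes):
                direction = truth.de_direction[key].get(gene)
                if direction == "up":
                    shift[i] = config.log2fc_effect
                elif direction == "down":
                    shift[i] = -config.log2fc_effect
        present = np.array([sid in present_lookup[g] for g in genes])
        for r in range(n_reps):
            col = f"{sid}.{r + 1}"
            log2 = baseline + shift + rng.normal(0.0, config.sigma_within,
                                                 size=n_genes)
            intensity_cols[col] = 2.0 ** log2
            dp = np.where(present,
                          rng.uniform(lo_p, hi_p, size=n_genes),
                          rng.uniform(lo_a, hi_a, size=n_genes))
            detection_cols[col] = dp

    intensity = pd.DataFrame(intensity_cols, index=genes)
    detection = pd.DataFrame(detection_cols, index=genes)
    study = ExpressionStudy(genes=genes, samples=samples,
                            intensity=intensity, detection_p=detection)
    study.validate()
    return study


# ---------------------------------------------------------------------------
# Sequence realization
# ---------------------------------------------------------------------------

def _random_sequences(rng: np.random.Generator, genes: list[str],
                      length: int, gc: float) -> dict[str, str]:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    codes = rng.choice(4, size=(len(genes), length), p=probs)
    rows = alphabet[codes]
    return {g: rows[i].tobytes().decode("ascii")
            for i, g in enumerate(genes)}


def base_probability(motif: str, gc: float) -> float:
    """i.i.d. probability of one exact motif occurrence per window."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2,
         "C": gc / 2, "G": gc / 2}
    out = 1.0
    for b in motif:
        out *= p[b]
    return out


def _count_occurrences(seq: str, motif: str) -> int:
    """Overlapping occurrence count of an exact motif."""
    count = start = 0
    while True:
        pos = seq.find(motif, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def _insert_motif(rng: np.random.Generator, seq: str, motif: str,
                  n_copies: int) -> str:
    """Overwrite n_copies non-overlapping positions with the motif."""
    k = len(motif)
    arr = list(seq)
    taken: list[tuple[int, int]] = []
    placed = 0
    attempts = 0
    while placed < n_copies and attempts < 100 * max(1, n_copies):
        attempts += 1
        pos = int(rng.integers(0, len(seq) - k + 1))
        if any(pos < e and pos + k > s for s, e in taken):
            continue
        arr[pos:pos + k] = motif
        taken.append((pos, pos + k))
        placed += 1
    if placed < n_copies:
        logger.warning("could only place %d/%d motif copies", placed,
                       n_copies)
    return "".join(arr)


def generate_sequences(config: SimConfig, universe: GeneUniverse,
                       truth: SimTruth, species: str = "A",
                       ) -> tuple[dict[str, str], dict[str, str]]:
    """One species' promoter and 3'UTR sequences with planted motifs.

    Backgrounds are i.i.d. at the configured GC content.  For each
    planted promoter motif targeting one of this species' gene sets,
    extra exact copies overwrite bases at non-overlapping random
    positions (preserving promoter length) until the *measured*
    set-vs-genome occurrence ratio is expected to equal the requested
    fold — the insertion count corrects for the set's own contribution
    to the genome denominator.  Planted 3'UTR motifs place one copy in
    the configured fraction of the target set's UTRs.
    """
    sp = species.lower()
    genes = sorted(universe.species_a_ids if sp == "a"
                   else universe.species_b_ids)
    rng = config.rng(f"sequences_{sp}")
    promoters = _random_sequences(rng, genes, config.promoter_length,
                                  config.gc_content)
    utrs = _random_sequences(rng, genes, config.utr_length,
                             config.gc_content)

    k = config.kmer_k
    win_per_gene = config.promoter_length - k + 1
    w_genome = win_per_gene * len(genes)
    for motif, label, fold in config.planted_motifs:
        if not label.startswith(f"{sp}_"):
            continue
        targets = sorted(truth.gene_set(label))
        if not targets:
            logger.warning("planted motif %s: set %s is empty", motif, label)
            continue
        w_set = win_per_gene * len(targets)
        denom = 1.0 - fold * w_set / w_genome
        if denom <= 0:
            raise ConfigError(
                f"fold {fold} for motif {motif} infeasible: target set is "
                "too large a share of the genome"
            )
        # plant against the *measured* background occurrences so the
        # realized set-vs-genome ratio lands on the requested fold; the
        # denominator correction accounts for the insertions also
        # inflating the genome-wide frequency (the set is part of it)
        target_set = set(targets)
        c_set = sum(_count_occurrences(promoters[g], motif)
                    for g in targets)
        c_genome = c_set + sum(_count_occurrences(seq, motif)
                               for g, seq in promoters.items()
                               if g not in target_set)
        n_insert = int(round(
            (fold * c_genome * w_set / w_genome - c_set) / denom
        ))
        if n_insert <= 0:
            continue
        per_gene = rng.multinomial(n_insert,
                                   np.full(len(targets), 1 / len(targets)))
        for gene, copies in zip(targets, per_gene):
            if copies:
                promoters[gene] = _insert_motif(rng, promoters[gene], motif,
                                                int(copies))

    for motif, _cls, label, frac in config.planted_utr_motifs:
        if not label.startswith(f"{sp}_"):
            continue
        targets = sorted(truth.gene_set(label))
        n_hit = int(round(frac * len(targets)))
        if n_hit == 0:
            continue
        chosen = rng.choice(len(targets), size=n_hit, replace=False)
        for idx in chosen:
            gene = targets[idx]
            utrs[gene] = _insert_motif(rng, utrs[gene], motif, 1)
    return promoters, utrs


def default_utr_catalog(config: SimConfig) -> UtrMotifCatalog:
    """The editable stability-motif catalog, including any planted
    motifs not already present."""
    entries = list(DEFAULT_UTR_CATALOG)
    known = {seq for _, _, seq in entries}
    for motif, cls, label, _frac in config.planted_utr_motifs:
        if motif not in known:
            entries.append((f"planted_{motif}", cls, motif))
            known.add(motif)
    return UtrMotifCatalog(entries=entries)


# ---------------------------------------------------------------------------
# Dataset bundle and on-disk emission
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """In-memory bundle of one generated two-species dataset."""

    config: SimConfig
    universe: GeneUniverse
    orthologs: OrthologGroupMap
    truth: SimTruth
    study_a: ExpressionStudy
    study_b: ExpressionStudy
    promoters_a: dict[str, str]
    promoters_b: dict[str, str]
    utrs_a: dict[str, str]
    utrs_b: dict[str, str]
    catalog: UtrMotifCatalog


def generate_dataset(config: SimConfig) -> Dataset:
    """Run every generator stage for one config."""
    universe, orthos, truth = generate_universe(config)
    study_a = generate_expression(config, universe, truth, "A")
    study_b = generate_expression(config, universe, truth, "B")
    promoters_a, utrs_a = generate_sequences(config, universe, truth, "A")
    promoters_b, utrs_b = generate_sequences(config, universe, truth, "B")
    return Dataset(
        config=config, universe=universe, orthologs=orthos, truth=truth,
        study_a=study_a, study_b=study_b,
        promoters_a=promoters_a, promoters_b=promoters_b,
        utrs_a=utrs_a, utrs_b=utrs_b,
        catalog=default_utr_catalog(config),
    )


def write_dataset(config: SimConfig, outdir, force: bool = False) -> dict:
    """Emit every interchange file plus the truth sidecar and manifest.

    Refuses to write into an existing non-empty directory unless
    ``force`` is set.  Returns the manifest (paths plus config hash).
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(
            f"output directory {outdir} is not empty (use force=True)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config)

    files: dict[str, str] = {}

    def path(name: str) -> Path:
        files[name] = name
        return outdir / name

    for sp, study in (("a", ds.study_a), ("b", ds.study_b)):
        write_expression_study(study,
                               path(f"{sp}_intensity.tsv"),
                               path(f"{sp}_detection.tsv"),
                               path(f"{sp}_samples.tsv"))
    write_ortholog_groups(ds.orthologs, path("orthologs.tsv"))
    ann_a = {g: ds.universe.annotations[g]
             for g in sorted(ds.universe.species_a_ids)}
    ann_b = {g: ds.universe.annotations[g]
             for g in sorted(ds.universe.species_b_ids)}
    write_annotations(ann_a, path("a_annotations.tsv"))
    write_annotations(ann_b, path("b_annotations.tsv"))
    write_fasta_set(ds.promoters_a, path("a_promoters.fasta"))
    write_fasta_set(ds.promoters_b, path("b_promoters.fasta"))
    write_fasta_set(ds.utrs_a, path("a_utrs.fasta"))
    write_fasta_set(ds.utrs_b, path("b_utrs.fasta"))
    pd.DataFrame(ds.catalog.entries,
                 columns=["name", "motif_class", "sequence"]).to_csv(
        path("utr_motifs.tsv"), sep="\t", index=False)
    with open(path("truth.json"), "w") as fh:
        json.dump(ds.truth.to_dict(), fh, indent=1, sort_keys=True)

    manifest = {
        "config_digest": ds.config.digest(),
        "config": ds.config.to_dict(),
        "files": sorted(files),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=list)
    return manifest
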