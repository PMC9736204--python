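"""Synthetic three-group lymphoma cohort generator.

Generates complete cohorts — segmented copy-number profiles, per-caller
variant call lists, cell-level FISH signal records, and clinical outcome
tables — with the statistical structure the downstream analysis assumes,
plus the latent ground truth, so that every pipeline stage is testable
without patient data.

The three group templates emulate the published profiles of the study
groups:

* ``DHL_THL`` — MYC plus BCL2 and/or BCL6 rearranged; recurrent gains at
  1q25.2, 3q29, chr5, 6p25.3, chr7 (peak 7p22.3), chr8 (peak 8q23.3),
  chr12 (peak 12p12.2), 20q13.33; losses at 1p36.32 and 6q22.1; high
  per-gene mutation probabilities for BCL2, MYC, KMT2D, SOCS1, CREBBP,
  MEF2B, ARID1B, HIST1H1E; target mean panel burden 17.
* ``SHL`` — MYC rearranged alone; overlapping copy-number profile plus
  SHL-enriched gains at 9p13.3-q34.3 and 16p11.2; frequent MYC, DTX1,
  MEF2B, PIM1 mutations, no BCL2 mutations; target mean burden 10.
* ``MCAD`` — no rearrangements, MYC-cluster amplification; a single
  constitutive +8q24 gain; DDX3X/KMT2D/CREBBP/TP53 mutations, MYC unmutated.

Template regions are kept pairwise disjoint (chromosome-wide alterations and
their higher-frequency peaks are encoded as separate disjoint regions with a
short neutral gap) so every template region maps to exactly one recoverable
minimal common region.

The simulation genome is a miniature: the 13 chromosomes the templates
touch, 100 Mb each, with a coarse cytoband table carrying the band names
the study reports. Gene intervals are placed so that no gene straddles a
template-region boundary, which makes the noise-free generator exactly
recoverable by the downstream pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fish import classify_subtype
from .variants import VariantCandidate

__all__ = [
    "GroupTemplate",
    "CohortConfig",
    "CohortBundle",
    "ConfigurationError",
    "DEFAULT_GENOME",
    "DEFAULT_BCL6_EXONS",
    "default_panel",
    "default_gene_map",
    "default_cytobands",
    "default_templates",
    "calibrate_burden",
    "sample_cna_profile",
    "sample_variants",
    "sample_fish",
    "sample_clinical",
    "generate_cohort",
]

MB = 1_000_000
GROUPS = ("DHL_THL", "SHL", "MCAD")

#: miniature simulation genome: the chromosomes the group templates touch
DEFAULT_GENOME: Tuple[Tuple[str, int], ...] = tuple(
    (f"chr{c}", 100 * MB) for c in (1, 3, 5, 6, 7, 8, 9, 12, 14, 15, 16, 18, 20)
)

#: micro genome for algorithm tests where per-base oracles must be cheap
TOY_GENOME: Tuple[Tuple[str, int], ...] = (("chrA", 5_000), ("chrB", 5_000))

_CYTOBANDS = {
    "chr1": [
        (0, 5, "p36.32"), (5, 15, "p36.1"), (15, 30, "p31.1"), (30, 50, "p11"),
        (50, 60, "q21.1"), (60, 75, "q25.2"), (75, 100, "q44"),
    ],
    "chr3": [(0, 30, "p13"), (30, 50, "p11"), (50, 70, "q26.1"), (70, 100, "q29")],
    "chr5": [(0, 50, "p15"), (50, 100, "q31")],
    "chr6": [
        (0, 10, "p25.3"), (10, 30, "p22.3"), (30, 50, "p11"),
        (50, 70, "q22.1"), (70, 100, "q23"),
    ],
    "chr7": [(0, 20, "p22.3"), (20, 50, "p11"), (50, 100, "q31")],
    "chr8": [(0, 30, "p23"), (30, 50, "p11"), (50, 70, "q23.3"), (70, 100, "q24")],
    "chr9": [(0, 20, "p13.3"), (20, 40, "p11"), (40, 60, "q21.11"), (60, 100, "q34.3")],
    "chr12": [(0, 20, "p12.2"), (20, 40, "p11"), (40, 100, "q13")],
    "chr14": [(0, 30, "q11.2"), (30, 100, "q31.1")],
    "chr15": [(0, 40, "q11"), (40, 70, "q22.31"), (70, 100, "q26")],
    "chr16": [(0, 30, "p11.2"), (30, 100, "q11")],
    "chr18": [(0, 10, "p11.31"), (10, 30, "p11.23"), (30, 100, "q11")],
    "chr20": [(0, 40, "p11"), (40, 80, "q11"), (80, 100, "q13.33")],
}

# genes printed in the study's results/figures/tables; the remainder of the
# 115-gene aggressive-B-cell-lymphoma panel is filled with synthetic names
_NAMED_GENES = [
    "MYC", "BCL2", "BCL6", "KMT2D", "CREBBP", "SOCS1", "MEF2B", "ARID1B",
    "HIST1H1E", "DTX1", "PIM1", "PAX5", "DDX3X", "TCF3", "HLA-A", "TP53",
    "BTG2", "EZH2", "IGLL5", "FOXO1", "UBE2A", "KMT2C", "EP300", "TET2",
    "MYD88", "CD274", "PRKCB", "STAT3", "P2RY8", "TNFRSF14", "CDK6",
    "CDKN2A", "PTEN", "ARID1A", "CD79B", "NOTCH1", "AICDA",
]
PANEL_SIZE = 115

GENE_LENGTH = 100_000
# pinned loci (miniature genome coordinates); MYC inside the 8q24 band so the
# constitutive MCAD gain covers it, BCL6 where its exon model lives
_PINNED_GENES = {
    "MYC": ("chr8", 75 * MB + 200_000),
    "BCL6": ("chr3", 72 * MB + 200_000),
    "BCL2": ("chr18", 60 * MB + 200_000),
    "KMT2D": ("chr12", 45 * MB + 200_000),
    "CREBBP": ("chr16", 3 * MB + 200_000),
}

_BCL6_START = 72 * MB + 200_000
#: 0-based half-open intervals of BCL6 exons 3-10 (the covered exons)
DEFAULT_BCL6_EXONS: Tuple[Tuple[int, int], ...] = tuple(
    (_BCL6_START + (i - 1) * 10_000, _BCL6_START + (i - 1) * 10_000 + 2_000)
    for i in range(3, 11)
)

DEFAULT_CONSEQUENCE_PROBS = {
    "missense": 0.60,
    "frameshift": 0.20,
    "stop_gained": 0.12,
    "splice": 0.08,
}

_BASES = ("A", "C", "G", "T")


class ConfigurationError(ValueError):
    """Invalid cohort configuration or template/panel mismatch."""


def default_panel() -> List[str]:
    """The 115-gene panel: study-named genes plus synthetic filler names."""
    filler = [f"GENE{i:03d}" for i in range(1, PANEL_SIZE - len(_NAMED_GENES) + 1)]
    return _NAMED_GENES + filler


def default_cytobands() -> pd.DataFrame:
    """Miniature UCSC-style cytoband table for the simulation genome."""
    rows = []
    for chrom, bands in _CYTOBANDS.items():
        for s, e, name in bands:
            rows.append(
                {"chrom": chrom, "start": s * MB, "end": e * MB,
                 "band": name, "stain": "gneg"}
            )
    return pd.DataFrame(rows)


def default_gene_map(
    panel: Optional[Sequence[str]] = None,
    genome: Sequence[Tuple[str, int]] = DEFAULT_GENOME,
) -> Dict[str, Tuple[str, int, int]]:
    """Deterministic gene placement on the simulation genome.

    Pinned study genes keep their curated loci; the rest tile the genome at
    2 Mb spacing, offset so no gene crosses a 5 Mb template-region boundary.
    """
    panel = list(panel) if panel is not None else default_panel()
    chroms = [c for c, _ in genome]
    lengths = dict(genome)
    gene_map: Dict[str, Tuple[str, int, int]] = {}
    taken = set()
    for gene, (chrom, start) in _PINNED_GENES.items():
        if gene in panel:
            gene_map[gene] = (chrom, start, start + GENE_LENGTH)
            taken.add((chrom, start))
    slot = 0
    for gene in panel:
        if gene in gene_map:
            continue
        while True:
            chrom = chroms[slot % len(chroms)]
            start = 1_200_000 + (slot // len(chroms)) * 2 * MB
            slot += 1
            if start + GENE_LENGTH <= lengths[chrom] and (chrom, start) not in taken:
                break
        gene_map[gene] = (chrom, start, start + GENE_LENGTH)
        taken.add((chrom, start))
    return gene_map


# ---------------------------------------------------------------------------
# templates and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FishProfile:
    """Per-group probabilities of the FISH-detectable lesions."""

    p_myc_r: float
    p_bcl2_r: float
    p_bcl6_r: float
    myc_amp: bool
    p_myc_igh: float = 0.0
    require_partner: bool = False  # force BCL2 and/or BCL6 alongside MYC-R


@dataclass(frozen=True)
class OutcomeProfile:
    """Response / relapse / survival distribution parameters (months)."""

    p_cr: float
    p_pr: float
    p_relapse: float
    p_gcb: float
    os_median_favorable: float = 60.0
    os_median_adverse: float = 15.0
    followup_min: float = 24.0
    followup_max: float = 96.0


@dataclass(frozen=True)
class GroupTemplate:
    """Generative template of one study group."""

    group_label: str
    cna_regions: Tuple[Tuple[str, int, int, str, float], ...]
    gene_mutation_probs: Mapping[str, float]
    target_mean_burden: float
    fish_profile: FishProfile
    outcome_profile: OutcomeProfile

    def validate(self, panel: Sequence[str], genome: Sequence[Tuple[str, int]]):
        if self.group_label not in GROUPS:
            raise ConfigurationError(f"unknown group label {self.group_label!r}")
        lengths = dict(genome)
        seen: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end, direction, freq in self.cna_regions:
            if chrom not in lengths:
                raise ConfigurationError(f"region chromosome {chrom!r} not in genome")
            if not (0 <= start < end <= lengths[chrom]):
                raise ConfigurationError(
                    f"invalid region interval {chrom}:{start}-{end}"
                )
            if direction not in ("gain", "loss"):
                raise ConfigurationError(f"bad region direction {direction!r}")
            if not 0.0 <= freq <= 1.0:
                raise ConfigurationError("region frequency must be in [0, 1]")
            for s, e in seen.get(chrom, []):
                if start < e and end > s:
                    raise ConfigurationError(
                        f"template regions overlap on {chrom}: "
                        f"({s},{e}) vs ({start},{end})"
                    )
            seen.setdefault(chrom, []).append((start, end))
        panel_set = set(panel)
        for gene, p in self.gene_mutation_probs.items():
            if gene not in panel_set:
                raise ConfigurationError(f"template gene {gene!r} not in panel")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"gene probability out of [0,1]: {gene}")
        if self.target_mean_burden < 0:
            raise ConfigurationError("target_mean_burden must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings."""

    group_sizes: Mapping[str, int]
    panel: Tuple[str, ...] = tuple(default_panel())
    genome: Tuple[Tuple[str, int], ...] = DEFAULT_GENOME
    caller_count: int = 5
    caller_sensitivity: Tuple[float, ...] = (0.9, 0.9, 0.9, 0.9, 0.9)
    artifact_rate: float = 2.0
    germline_rate: float = 3.0
    consequence_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_PROBS)
    )
    seed: int = 0

    def validate(self):
        if self.caller_count < 1:
            raise ConfigurationError("caller_count must be >= 1")
        if len(self.caller_sensitivity) != self.caller_count:
            raise ConfigurationError(
                "caller_sensitivity must have one entry per caller"
            )
        if any(not 0.0 <= s <= 1.0 for s in self.caller_sensitivity):
            raise ConfigurationError("caller sensitivities must be in [0, 1]")
        for g, size in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group label {g!r}")
            if size < 0:
                raise ConfigurationError("group sizes must be >= 0")
        if len(set(self.panel)) != len(self.panel):
            raise ConfigurationError("panel gene names must be unique")
        if self.artifact_rate < 0 or self.germline_rate < 0:
            raise ConfigurationError("rates must be non-negative")


@dataclass
class CohortBundle:
    """Everything the generator emits for one cohort, plus latent truth."""

    segments: pd.DataFrame  # sample, chrom, start, end, num_probes, value
    caller_calls: Dict[str, List[List[VariantCandidate]]]
    fish: pd.DataFrame  # case, probe, cell_index, pattern, signal_count
    clinical: pd.DataFrame
    truth: Dict[str, dict]

    @property
    def samples(self) -> List[str]:
        return list(self.truth.keys())


def _probs(named: Mapping[str, float], panel: Sequence[str], target: float):
    """Named genes keep their stated probabilities; filler genes share the rest."""
    probs = {g: 0.0 for g in panel}
    probs.update(named)
    named_sum = sum(named.values())
    filler = [g for g in panel if g not in named]
    if filler and target > named_sum:
        per = (target - named_sum) / len(filler)
        for g in filler:
            probs[g] = per
    return probs


def default_templates(
    panel: Optional[Sequence[str]] = None,
) -> List[GroupTemplate]:
    """The three study-group templates at their reported frequencies."""
    panel = list(panel) if panel is not None else default_panel()

    dhl_regions = (
        ("chr1", 0, 5 * MB, "loss", 0.33),
        ("chr1", 60 * MB, 75 * MB, "gain", 0.56),
        ("chr3", 70 * MB, 100 * MB, "gain", 0.56),
        ("chr5", 0, 100 * MB, "gain", 0.44),
        ("chr6", 0, 10 * MB, "gain", 0.44),
        ("chr6", 50 * MB, 70 * MB, "loss", 0.33),
        ("chr7", 0, 20 * MB, "gain", 0.56),
        ("chr7", 25 * MB, 100 * MB, "gain", 0.44),
        ("chr8", 0, 45 * MB, "gain", 0.44),
        ("chr8", 50 * MB, 70 * MB, "gain", 0.56),
        ("chr8", 75 * MB, 100 * MB, "gain", 0.44),
        ("chr12", 0, 20 * MB, "gain", 0.67),
        ("chr12", 25 * MB, 100 * MB, "gain", 0.67),
        ("chr20", 80 * MB, 100 * MB, "gain", 0.56),
    )
    shl_regions = (
        ("chr1", 0, 10 * MB, "loss", 0.40),
        ("chr1", 15 * MB, 30 * MB, "loss", 0.50),
        ("chr1", 35 * MB, 60 * MB, "loss", 0.40),
        ("chr3", 0, 45 * MB, "gain", 0.50),
        ("chr3", 50 * MB, 70 * MB, "gain", 0.60),
        ("chr3", 75 * MB, 100 * MB, "gain", 0.50),
        ("chr6", 0, 30 * MB, "gain", 0.40),
        ("chr6", 50 * MB, 100 * MB, "loss", 0.30),
        ("chr9", 0, 20 * MB, "gain", 0.40),
        ("chr9", 40 * MB, 100 * MB, "gain", 0.40),
        ("chr12", 0, 20 * MB, "gain", 0.80),
        ("chr12", 25 * MB, 100 * MB, "gain", 0.50),
        ("chr14", 0, 100 * MB, "gain", 0.40),
        ("chr15", 40 * MB, 70 * MB, "loss", 0.40),
        ("chr16", 0, 30 * MB, "gain", 0.50),
        ("chr18", 0, 30 * MB, "loss", 0.40),
        ("chr20", 0, 100 * MB, "gain", 0.50),
    )
    mcad_regions = (("chr8", 70 * MB, 100 * MB, "gain", 1.0),)

    dhl_genes = {
        "BCL2": 0.89, "MYC": 0.78, "KMT2D": 0.78, "SOCS1": 0.67,
        "CREBBP": 0.56, "MEF2B": 0.44, "ARID1B": 0.44, "HIST1H1E": 0.44,
    }
    shl_genes = {
        "MYC": 0.83, "DTX1": 0.67, "MEF2B": 0.50, "PIM1": 0.50,
        "PAX5": 0.33, "BCL2": 0.0,
    }
    mcad_genes = {
        "DDX3X": 1.0, "KMT2D": 0.67, "CREBBP": 0.67, "TP53": 0.67, "MYC": 0.0,
    }

    return [
        GroupTemplate(
            group_label="DHL_THL",
            cna_regions=dhl_regions,
            gene_mutation_probs=_probs(dhl_genes, panel, 17.0),
            target_mean_burden=17.0,
            fish_profile=FishProfile(1.0, 0.7, 0.5, False, 0.4, require_partner=True),
            outcome_profile=OutcomeProfile(0.50, 0.30, 0.30, 0.80),
        ),
        GroupTemplate(
            group_label="SHL",
            cna_regions=shl_regions,
            gene_mutation_probs=_probs(shl_genes, panel, 10.0),
            target_mean_burden=10.0,
            fish_profile=FishProfile(1.0, 0.0, 0.0, False, 0.7),
            outcome_profile=OutcomeProfile(0.60, 0.25, 0.25, 0.60),
        ),
        GroupTemplate(
            group_label="MCAD",
            cna_regions=mcad_regions,
            gene_mutation_probs=_probs(mcad_genes, panel, 12.0),
            target_mean_burden=12.0,
            fish_profile=FishProfile(0.0, 0.0, 0.0, True, 0.0),
            outcome_profile=OutcomeProfile(0.34, 0.33, 0.50, 0.50),
        ),
    ]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_burden(
    gene_mutation_probs: Mapping[str, float],
    target_mean_burden: float,
    tol: float = 1e-9,
) -> Dict[str, float]:
    """Rescale per-gene Bernoulli probabilities so they sum to the target.

    Under independent per-gene mutation the expected panel burden equals the
    sum of the probabilities. Probabilities are scaled proportionally; any
    that would exceed 1 are clipped and the remainder re-scaled iteratively
    until the sum matches ``target_mean_burden`` within ``tol``.
    """
    probs = {g: float(p) for g, p in gene_mutation_probs.items()}
    n = len(probs)
    if target_mean_burden > n:
        raise ConfigurationError(
            f"target burden {target_mean_burden} exceeds panel size {n}"
        )
    total = sum(probs.values())
    if total <= 0 and target_mean_burden > 0:
        raise ConfigurationError("cannot calibrate: all probabilities are zero")
    if target_mean_burden == 0:
        return {g: 0.0 for g in probs}
    clipped = set()
    for _ in range(n + 1):
        free_sum = sum(p for g, p in probs.items() if g not in clipped)
        remaining = target_mean_burden - len(clipped)
        if free_sum <= 0:
            break
        scale = remaining / free_sum
        newly_clipped = False
        for g in probs:
            if g in clipped:
                continue
            v = probs[g] * scale
            if v >= 1.0:
                probs[g] = 1.0
                clipped.add(g)
                newly_clipped = True
            else:
                probs[g] = v
        if not newly_clipped:
            break
    if abs(sum(probs.values()) - target_mean_burden) > tol:
        raise ConfigurationError(
            "burden calibration failed to converge (target infeasible "
            "after clipping)"
        )
    return probs


# ---------------------------------------------------------------------------
# per-sample sampling
# ---------------------------------------------------------------------------

def sample_cna_profile(
    template: GroupTemplate,
    genome: Sequence[Tuple[str, int]],
    rng: np.random.Generator,
) -> List[dict]:
    """Draw one sample's segment rows (dicts) and its true altered regions.

    Each template region is present independently with its stated frequency;
    the rest of the genome is tiled with neutral segments. Returns
    ``(segment_rows, true_regions)``.
    """
    lengths = dict(genome)
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {c: [] for c in lengths}
    true_regions = []
    for chrom, start, end, direction, freq in template.cna_regions:
        if chrom not in lengths or not (0 <= start < end <= lengths[chrom]):
            raise ConfigurationError(f"region off genome: {chrom}:{start}-{end}")
        if rng.random() < freq:
            by_chrom[chrom].append((start, end, direction))
            true_regions.append(
                {"chrom": chrom, "start": start, "end": end, "direction": direction}
            )
    rows = []
    for chrom, length in genome:
        altered = sorted(by_chrom[chrom])
        cursor = 0
        for start, end, direction in altered:
            if start > cursor:
                rows.append(_segment_row(chrom, cursor, start, "neutral", rng))
            rows.append(_segment_row(chrom, start, end, direction, rng))
            cursor = end
        if cursor < length:
            rows.append(_segment_row(chrom, cursor, length, "neutral", rng))
    return rows, true_regions


def _segment_row(chrom, start, end, direction, rng):
    if direction == "gain":
        value = rng.uniform(0.4, 0.7)
    elif direction == "loss":
        value = rng.uniform(-0.7, -0.4)
    else:
        value = float(np.clip(rng.normal(0.0, 0.03), -0.1, 0.1))
    return {
        "chrom": chrom,
        "start": int(start),
        "end": int(end),
        "num_probes": max(10, (end - start) // 50_000),
        "value": round(float(value), 4),
    }


def _draw_variant_site(gene, gene_map, rng, used):
    chrom, gstart, gend = gene_map[gene]
    if gene == "BCL6":
        # covered exons only, so true BCL6 variants survive the exon mask
        exon = DEFAULT_BCL6_EXONS[rng.integers(0, len(DEFAULT_BCL6_EXONS))]
        lo, hi = exon
    else:
        lo, hi = gstart, gend
    for _ in range(100):
        pos = int(rng.integers(lo, hi)) + 1  # 1-based
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            ref = _BASES[rng.integers(0, 4)]
            alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
            return chrom, pos, ref, alt
    raise RuntimeError("could not place variant without position collision")


def sample_variants(
    template: GroupTemplate,
    panel: Sequence[str],
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "S",
    gene_map: Optional[Mapping[str, Tuple[str, int, int]]] = None,
    calibrated_probs: Optional[Mapping[str, float]] = None,
):
    """Draw one sample's true somatic variants and per-caller call lists.

    Returns ``(truth_genes, per_caller_lists)``. True somatic variants (one
    per mutated gene) are annotated so they always satisfy at least one
    somatic criterion; each caller detects each true variant independently
    with its sensitivity. Injected artifacts carry 1-2 caller flags by
    construction; injected germline variants carry population AF >= 0.01.
    """
    gene_map = gene_map or default_gene_map(panel, config.genome)
    probs = calibrated_probs or calibrate_burden(
        template.gene_mutation_probs, template.target_mean_burden
    )
    cons = list(config.consequence_probs.items())
    cons_names = [c for c, _ in cons]
    cons_p = np.array([p for _, p in cons], dtype=float)
    cons_p = cons_p / cons_p.sum()
    used: set = set()
    per_caller: List[List[VariantCandidate]] = [
        [] for _ in range(config.caller_count)
    ]
    truth_genes: List[str] = []

    def emit(cand: VariantCandidate, detect_probs):
        for i, p in enumerate(detect_probs):
            if rng.random() < p:
                flags = [False] * config.caller_count
                flags[i] = True
                per_caller[i].append(replace(cand, caller_flags=tuple(flags)))

    for gene in panel:
        p = probs.get(gene, 0.0)
        if rng.random() >= p:
            continue
        truth_genes.append(gene)
        chrom, pos, ref, alt = _draw_variant_site(gene, gene_map, rng, used)
        consequence = cons_names[rng.choice(len(cons_names), p=cons_p)]
        cosmic = rng.random() < 0.30
        literature = rng.random() < 0.15
        if consequence == "missense" and not (cosmic or literature):
            votes = int(rng.integers(2, 5))  # guaranteed damaging consensus
        elif consequence == "missense":
            votes = int(rng.integers(0, 5))
        else:
            votes = 0
        cand = VariantCandidate(
            sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref,
            alt=alt, consequence=consequence,
            caller_flags=(False,) * config.caller_count,
            cosmic_somatic=cosmic, literature_somatic=literature,
            damaging_votes=votes, population_af=None,
        )
        emit(cand, config.caller_sensitivity)

    # sequencing artifacts: concentrated on 1-2 callers, never reach consensus
    for _ in range(rng.poisson(config.artifact_rate)):
        gene = panel[rng.integers(0, len(panel))]
        chrom, pos, ref, alt = _draw_variant_site(gene, gene_map, rng, used)
        cand = VariantCandidate(
            sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref,
            alt=alt,
            consequence=["missense", "synonymous", "other"][rng.integers(0, 3)],
            caller_flags=(False,) * config.caller_count,
            cosmic_somatic=False, literature_somatic=False,
            damaging_votes=int(rng.integers(0, 2)), population_af=None,
        )
        k = int(rng.integers(1, 3))
        callers = rng.choice(config.caller_count, size=k, replace=False)
        for i in callers:
            flags = [False] * config.caller_count
            flags[i] = True
            per_caller[i].append(replace(cand, caller_flags=tuple(flags)))

    # germline contamination: high population AF, classified out as SNPs
    for _ in range(rng.poisson(config.germline_rate)):
        gene = panel[rng.integers(0, len(panel))]
        chrom, pos, ref, alt = _draw_variant_site(gene, gene_map, rng, used)
        cand = VariantCandidate(
            sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref,
            alt=alt,
            consequence=["missense", "synonymous"][rng.integers(0, 2)],
            caller_flags=(False,) * config.caller_count,
            cosmic_somatic=False, literature_somatic=False,
            damaging_votes=int(rng.integers(0, 5)),
            population_af=round(float(rng.uniform(0.01, 0.5)), 4),
        )
        emit(cand, config.caller_sensitivity)

    return truth_genes, per_caller


def _cell_patterns(n, n_positive, positive_label, rng):
    patterns = np.array(
        [positive_label] * n_positive + ["colocalized"] * (n - n_positive),
        dtype=object,
    )
    rng.shuffle(patterns)
    return patterns


def sample_fish(
    template: GroupTemplate, rng: np.random.Generator, case_id: str = "S"
):
    """Draw one case's FISH truth flags and cell-level signal records.

    Returns ``(truth_flags, rows)`` where ``truth_flags`` holds the drawn
    myc_r/bcl2_r/bcl6_r/myc_amp/myc_igh booleans and ``rows`` the cell-level
    table rows (>= 100 cells per probe). Positive probes receive a split-cell
    fraction drawn well above the 10% threshold; negatives stay below it.
    Amplified cases show > 10 MYC signals in an above-threshold cell
    fraction.
    """
    fp = template.fish_profile
    myc_r = rng.random() < fp.p_myc_r
    bcl2_r = rng.random() < fp.p_bcl2_r
    bcl6_r = rng.random() < fp.p_bcl6_r
    if fp.require_partner and myc_r and not (bcl2_r or bcl6_r):
        bcl2_r = True  # the double/triple-hit group always has a partner lesion
    myc_amp = bool(fp.myc_amp) and not myc_r
    myc_igh = myc_r and rng.random() < fp.p_myc_igh
    flags = {
        "myc_r": myc_r, "bcl2_r": bcl2_r, "bcl6_r": bcl6_r,
        "myc_amp": myc_amp, "myc_igh": myc_igh,
    }
    rows = []
    probe_flags = [
        ("MYC_BA", myc_r, "split"),
        ("BCL2_BA", bcl2_r, "split"),
        ("BCL6_BA", bcl6_r, "split"),
        ("MYC_IGH_FUSION", myc_igh, "fusion"),
    ]
    for probe, positive, label in probe_flags:
        n = int(rng.integers(100, 131))
        if positive:
            frac = rng.uniform(0.2, 0.8)
            n_pos = int(round(frac * n))
        else:
            frac = rng.uniform(0.0, 0.05)
            n_pos = int(math.floor(frac * n))
        patterns = _cell_patterns(n, n_pos, label, rng)
        if probe == "MYC_BA" and myc_amp:
            n_high = int(round(rng.uniform(0.2, 0.6) * n))
            signals = np.concatenate(
                [rng.integers(11, 31, size=n_high), rng.integers(2, 7, size=n - n_high)]
            )
            rng.shuffle(signals)
        else:
            signals = rng.integers(2, 7, size=n)
        for i in range(n):
            rows.append(
                {
                    "case": case_id,
                    "probe": probe,
                    "cell_index": i,
                    "pattern": patterns[i],
                    "signal_count": int(signals[i]),
                }
            )
    return flags, rows


def sample_clinical(
    template: GroupTemplate, rng: np.random.Generator, case_id: str = "S"
) -> dict:
    """Draw one case's clinical record (response, relapse, survival, IHC)."""
    op = template.outcome_profile
    u = rng.random()
    if u < op.p_cr:
        response = "CR"
    elif u < op.p_cr + op.p_pr:
        response = "PR"
    else:
        response = "other"
    relapse = bool(response == "CR" and rng.random() < op.p_relapse)
    favorable = response == "CR" and not relapse
    median = op.os_median_favorable if favorable else op.os_median_adverse
    death_time = rng.exponential(median / math.log(2))
    followup = rng.uniform(op.followup_min, op.followup_max)
    os_event = death_time <= followup
    os_time = max(0.1, round(min(death_time, followup), 1))
    gcb = rng.random() < op.p_gcb
    if gcb:
        cd10, bcl6_pct, mum1 = rng.uniform(40, 90), rng.uniform(0, 100), rng.uniform(0, 100)
    elif rng.random() < 0.5:
        cd10, bcl6_pct, mum1 = rng.uniform(0, 25), rng.uniform(0, 25), rng.uniform(0, 100)
    else:
        cd10, bcl6_pct, mum1 = rng.uniform(0, 25), rng.uniform(40, 90), rng.uniform(40, 90)
    return {
        "case_id": case_id,
        "group": template.group_label,
        "first_course_response": response,
        "relapse": relapse,
        "os_time": os_time,
        "os_event": bool(os_event),
        "ipi_group": ["low", "low_intermediate", "high_intermediate", "high"][
            rng.integers(0, 4)
        ],
        "cd10_pct": round(float(cd10), 1),
        "bcl6_pct": round(float(bcl6_pct), 1),
        "mum1_pct": round(float(mum1), 1),
    }


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig, templates: Sequence[GroupTemplate]
) -> CohortBundle:
    """Generate a complete cohort bundle, deterministic for a fixed seed."""
    config.validate()
    by_group = {t.group_label: t for t in templates}
    for g, size in config.group_sizes.items():
        if size > 0 and g not in by_group:
            raise ConfigurationError(f"no template provided for group {g!r}")
    for t in by_group.values():
        t.validate(config.panel, config.genome)

    rng = np.random.default_rng(config.seed)
    gene_map = default_gene_map(config.panel, config.genome)
    calibrated = {
        g: calibrate_burden(t.gene_mutation_probs, t.target_mean_burden)
        for g, t in by_group.items()
    }

    seg_rows: List[dict] = []
    fish_rows: List[dict] = []
    clin_rows: List[dict] = []
    caller_calls: Dict[str, List[List[VariantCandidate]]] = {}
    truth: Dict[str, dict] = {}

    for group in sorted(config.group_sizes):
        template = by_group.get(group)
        for i in range(config.group_sizes[group]):
            sid = f"{group}_{i + 1:03d}"
            rows, true_regions = sample_cna_profile(template, config.genome, rng)
            for r in rows:
                seg_rows.append({"sample": sid, **r})
            truth_genes, per_caller = sample_variants(
                template, config.panel, config, rng,
                sample_id=sid, gene_map=gene_map,
                calibrated_probs=calibrated[group],
            )
            caller_calls[sid] = per_caller
            flags, cells = sample_fish(template, rng, case_id=sid)
            fish_rows.extend(cells)
            clin = sample_clinical(template, rng, case_id=sid)
            clin_rows.append(clin)
            truth[sid] = {
                "group": group,
                "subtype": classify_subtype(
                    flags["myc_r"], flags["bcl2_r"], flags["bcl6_r"],
                    flags["myc_amp"],
                ),
                **flags,
                "mutated_genes": sorted(truth_genes),
                "cna_regions": true_regions,
                "prognosis": (
                    "favorable"
                    if clin["first_course_response"] == "CR" and not clin["relapse"]
                    else "adverse"
                ),
            }

    seg_cols = ["sample", "chrom", "start", "end", "num_probes", "value"]
    fish_cols = ["case", "probe", "cell_index", "pattern", "signal_count"]
    return CohortBundle(
        segments=pd.DataFrame(seg_rows, columns=seg_cols),
        caller_calls=caller_calls,
        fish=pd.DataFrame(fish_rows, columns=fish_cols),
        clinical=pd.DataFrame(clin_rows),
        truth=truth,
    )
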