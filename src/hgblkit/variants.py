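"""Multi-caller somatic variant consensus filtering and rule-based classification.

The filtering chain mirrors a targeted-panel somatic workflow for aggressive
B-cell lymphomas: per-caller call sets are merged on variant identity, only
variants seen by a minimum number of independent callers are retained,
BCL6 candidates are restricted to the covered exons (3-10), and the survivors
are classified into four categories (``mutation``, ``likely_SNP``, ``SNP``,
``likely_nonfunctional``). Only the ``mutation`` category enters downstream
analyses; the per-sample mutation burden is the number of distinct panel genes
carrying at least one selected mutation (not a per-megabase rate).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "VariantCandidate",
    "BurdenRecord",
    "AnnotationConflictError",
    "merge_caller_calls",
    "consensus_filter",
    "apply_bcl6_exon_mask",
    "classify_variant",
    "classify_variants",
    "select_mutations",
    "mutation_burden",
    "cohort_gene_frequency",
]

#: recognised consequence annotations
CONSEQUENCES = frozenset(
    {"missense", "frameshift", "splice", "stop_gained", "synonymous", "other"}
)
#: truncating consequences per somatic criterion (3); splice-region changes are
#: annotated "other" and deliberately excluded (conservative reading)
TRUNCATING = frozenset({"frameshift", "splice", "stop_gained"})

CATEGORIES = ("mutation", "likely_SNP", "SNP", "likely_nonfunctional")

N_PREDICTORS = 4  # PolyPhen2, SIFT, CADD, Mutation Assessor


class AnnotationConflictError(ValueError):
    """Two callers report the same variant key with different annotations."""


@dataclass(frozen=True)
class VariantCandidate:
    """One candidate variant of one sample with per-caller detection flags.

    ``pos`` is 1-based as in VCF. ``population_af`` is ``None`` when the
    population frequency is unknown.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    caller_flags: tuple
    cosmic_somatic: bool = False
    literature_somatic: bool = False
    damaging_votes: int = 0
    population_af: Optional[float] = None
    category: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not 0 <= self.damaging_votes <= N_PREDICTORS:
            raise ValueError(
                f"damaging_votes must be in 0..{N_PREDICTORS}, got {self.damaging_votes}"
            )

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def caller_count(self) -> int:
        return sum(bool(f) for f in self.caller_flags)

    @property
    def annotation(self):
        """Annotation fields that must agree when callers are merged."""
        return (
            self.gene,
            self.consequence,
            self.cosmic_somatic,
            self.literature_somatic,
            self.damaging_votes,
            self.population_af,
        )


@dataclass(frozen=True)
class BurdenRecord:
    """Panel mutation burden of one sample: genes with >= 1 selected mutation."""

    sample_id: str
    burden: int
    mutated_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.burden != len(self.mutated_genes):
            raise ValueError("burden must equal |mutated_genes|")


def normalize_variant(chrom: str, pos: int, ref: str, alt: str):
    """Left-align a (pos, ref, alt) pair by trimming shared context bases.

    Shared trailing bases are removed first, then shared leading bases (the
    position advances accordingly). At least one base is kept on each side.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def merge_caller_calls(
    per_caller_lists: Sequence[Sequence[VariantCandidate]],
    caller_count: Optional[int] = None,
) -> list:
    """Merge one sample's per-caller call lists into unified candidates.

    Variants identical on the normalized (chrom, pos, ref, alt) key collapse
    into a single candidate whose ``caller_flags`` is the union of detections.
    Annotations must agree across callers; a mismatch raises
    :class:`AnnotationConflictError`.
    """
    n = caller_count if caller_count is not None else len(per_caller_lists)
    merged: "OrderedDict[tuple, VariantCandidate]" = OrderedDict()
    flags: dict = {}
    for caller_idx, calls in enumerate(per_caller_lists):
        for cand in calls:
            key = normalize_variant(cand.chrom, cand.pos, cand.ref, cand.alt)
            if key in merged:
                prev = merged[key]
                if prev.sample_id != cand.sample_id:
                    raise ValueError("all per-caller lists must be from one sample")
                if prev.annotation != cand.annotation:
                    raise AnnotationConflictError(
                        f"conflicting annotations for variant {key}: "
                        f"{prev.annotation} vs {cand.annotation}"
                    )
            else:
                merged[key] = cand
                flags[key] = [False] * n
            flags[key][caller_idx] = True
    out = []
    for key, cand in merged.items():
        chrom, pos, ref, alt = key
        out.append(
            replace(
                cand,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                caller_flags=tuple(flags[key]),
            )
        )
    return out


def consensus_filter(
    candidates: Iterable[VariantCandidate], min_callers: int = 3
) -> list:
    """Keep candidates detected by at least ``min_callers`` callers (order-stable)."""
    return [c for c in candidates if c.caller_count >= min_callers]


def apply_bcl6_exon_mask(
    candidates: Iterable[VariantCandidate],
    bcl6_exons: Optional[Sequence[tuple]],
    gene: str = "BCL6",
) -> list:
    """Drop BCL6 candidates outside the covered exon intervals.

    ``bcl6_exons`` holds 0-based half-open (start, end) intervals for exons
    3-10, the only BCL6 exons with sequencing coverage. Other genes pass
    through untouched. A missing mask while BCL6 candidates are present is an
    error rather than silently keeping uncovered calls.
    """
    candidates = list(candidates)
    has_bcl6 = any(c.gene == gene for c in candidates)
    if bcl6_exons is None:
        if has_bcl6:
            raise ValueError(f"{gene} candidates present but no exon mask provided")
        return candidates
    intervals = sorted((int(s), int(e)) for s, e in bcl6_exons)
    out = []
    for c in candidates:
        if c.gene != gene:
            out.append(c)
            continue
        start0 = c.pos - 1  # VCF 1-based -> 0-based
        if any(s <= start0 < e for s, e in intervals):
            out.append(c)
    return out


def classify_variant(
    candidate: VariantCandidate,
    af_snp: float = 0.01,
    af_likely: float = 0.001,
) -> str:
    """Assign one of the four categories to a consensus-confident candidate.

    Evaluation order:

    a. population AF >= ``af_snp``  ->  ``SNP``;
    b. ``af_likely`` <= AF < ``af_snp`` without COSMIC/literature somatic
       evidence  ->  ``likely_SNP``;
    c. otherwise any of the four somatic criteria (disjunction) makes a
       ``mutation``: COSMIC-confirmed somatic; described in the literature as
       somatic/driver; truncating (frameshift, splice, stop gained); missense
       judged damaging by >= 2 of the 4 predictors;
    d. otherwise ``likely_nonfunctional``.
    """
    if candidate.consequence not in CONSEQUENCES:
        raise ValueError(f"unknown consequence {candidate.consequence!r}")
    af = candidate.population_af
    if af is not None and af >= af_snp:
        return "SNP"
    evidence = candidate.cosmic_somatic or candidate.literature_somatic
    if af is not None and af_likely <= af < af_snp and not evidence:
        return "likely_SNP"
    if (
        evidence
        or candidate.consequence in TRUNCATING
        or (candidate.consequence == "missense" and candidate.damaging_votes >= 2)
    ):
        return "mutation"
    return "likely_nonfunctional"


def classify_variants(
    candidates: Iterable[VariantCandidate],
    af_snp: float = 0.01,
    af_likely: float = 0.001,
) -> list:
    """Return candidates with their ``category`` field populated."""
    return [
        replace(c, category=classify_variant(c, af_snp=af_snp, af_likely=af_likely))
        for c in candidates
    ]


def select_mutations(classified: Iterable[VariantCandidate]) -> list:
    """Keep only candidates classified as ``mutation`` (order preserved)."""
    out = []
    for c in classified:
        if c.category is None:
            raise ValueError(f"unclassified candidate {c.key} in selection input")
        if c.category == "mutation":
            out.append(c)
    return out


def mutation_burden(
    sample_mutations: Iterable[VariantCandidate], panel: Sequence[str]
) -> BurdenRecord:
    """Count the distinct panel genes with at least one selected mutation."""
    panel_set = set(panel)
    genes = set()
    sample_id = ""
    for m in sample_mutations:
        if m.gene not in panel_set:
            raise ValueError(f"gene {m.gene!r} not in the configured panel")
        genes.add(m.gene)
        sample_id = m.sample_id
    return BurdenRecord(
        sample_id=sample_id, burden=len(genes), mutated_genes=frozenset(genes)
    )


def cohort_gene_frequency(
    selected_mutations: Iterable[VariantCandidate],
    cases: Sequence[str],
    group: Optional[Mapping[str, str]] = None,
    group_label: Optional[str] = None,
):
    """Per-gene fraction of cases carrying >= 1 selected mutation.

    ``cases`` lists the case ids of the cohort (or of one group when
    ``group``/``group_label`` restrict it). Returns a dict
    ``gene -> (mutated_cases, group_size, fraction)``; full precision is kept
    and display rounding to whole percent is left to the caller.
    """
    if group is not None and group_label is not None:
        cases = [c for c in cases if group.get(c) == group_label]
    if len(cases) == 0:
        raise ValueError("empty case group")
    case_set = set(cases)
    per_gene: dict = {}
    for m in selected_mutations:
        if m.sample_id in case_set:
            per_gene.setdefault(m.gene, set()).add(m.sample_id)
    n = len(cases)
    return {
        gene: (len(samples), n, len(samples) / n)
        for gene, samples in sorted(per_gene.items())
    }
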