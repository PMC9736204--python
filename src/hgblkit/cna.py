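"""Copy-number alteration calling, frequency profiles, and minimal common regions.

Input is segmented copy-number data (one row per sample segment with a
log2-ratio seg-mean or an integer copy number). Gains and losses are called
by threshold, genome-wide alteration frequencies are computed per group on a
fixed binning, and recurrent regions are summarised as minimal common
regions (MCRs): for each direction the group's altered segments are
projected onto the genome, the per-interval altered-sample count profile is
built, and

* every plateau of the count profile that is a strict local maximum and
  reaches the recurrence threshold is reported as a *peak* MCR, and
* every maximal run of above-threshold intervals spanning more than one
  plateau is additionally reported as a broad MCR whose frequency is the
  fraction of samples whose altered segments cover the entire run.

This reproduces the reporting style "+chr.7 (44%) with a peak at 7p22.3
(56%)". Every reported region is contained in the altered segments of each
of its contributing samples; consequently adjacent intervals are merged only
when the same samples contribute to both.

Coordinates are 0-based half-open internally; SEG files are converted at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import fisher_exact_two_sided, benjamini_hochberg

__all__ = [
    "McrRegion",
    "call_cna_states",
    "bin_genome",
    "alteration_frequency",
    "find_mcrs",
    "label_cytoband",
    "compare_cna_groups",
]

GAIN_LOG2 = 0.3
LOSS_LOG2 = -0.3
DEFAULT_MIN_FREQ = 0.3
DEFAULT_BIN_SIZE = 1_000_000
DIRECTIONS = ("gain", "loss")


@dataclass(frozen=True)
class McrRegion:
    """A minimal common region of recurrent gain or loss."""

    chrom: str
    start: int
    end: int
    direction: str
    frequency: float
    n_samples: int
    cytoband_label: str = ""
    is_peak: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("MCR end must exceed start")
        if not 0.0 < self.frequency <= 1.0:
            raise ValueError("MCR frequency must be in (0, 1]")


def call_cna_states(
    segments: pd.DataFrame,
    gain_log2: float = GAIN_LOG2,
    loss_log2: float = LOSS_LOG2,
    integer_cn: bool = False,
) -> pd.DataFrame:
    """Assign gain/loss/neutral calls to segments.

    log2-ratio input: gain iff value >= ``gain_log2``, loss iff value <=
    ``loss_log2``. Integer copy-number input (``integer_cn=True``): gain iff
    CN >= 3, loss iff CN <= 1, diploid baseline.
    """
    values = segments["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("segment values must be finite")
    out = segments.copy()
    if integer_cn:
        call = np.where(values >= 3, "gain", np.where(values <= 1, "loss", "neutral"))
    else:
        call = np.where(
            values >= gain_log2, "gain", np.where(values <= loss_log2, "loss", "neutral")
        )
    out["call"] = call
    return out


def bin_genome(
    genome: Sequence[Tuple[str, int]], bin_size: int = DEFAULT_BIN_SIZE
) -> pd.DataFrame:
    """Tile each chromosome with half-open bins; the last bin is truncated."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    rows = []
    for chrom, length in genome:
        start = 0
        while start < length:
            end = min(start + bin_size, length)
            rows.append({"chrom": chrom, "start": start, "end": end})
            start = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _sample_direction_intervals(
    calls: pd.DataFrame, direction: str
) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    """Per chromosome, per sample: merged altered intervals for one direction."""
    altered = calls[calls["call"] == direction]
    out: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    for (chrom, sample), df in altered.groupby(["chrom", "sample"], sort=True):
        ivs = sorted(zip(df["start"].astype(int), df["end"].astype(int)))
        merged: List[Tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out.setdefault(chrom, {})[sample] = merged
    return out


def alteration_frequency(
    calls: pd.DataFrame,
    bins: pd.DataFrame,
    group_samples: Sequence[str],
    direction: str,
) -> pd.DataFrame:
    """Per-bin fraction of group samples with >= 1 bp of altered overlap."""
    group_samples = list(group_samples)
    if not group_samples:
        raise ValueError("empty sample group")
    sub = calls[calls["sample"].isin(group_samples)]
    per_chrom = _sample_direction_intervals(sub, direction)
    n = len(group_samples)
    fracs = np.zeros(len(bins), dtype=float)
    for i, (chrom, bstart, bend) in enumerate(
        zip(bins["chrom"], bins["start"], bins["end"])
    ):
        hit = 0
        for ivs in per_chrom.get(chrom, {}).values():
            if any(s < bend and e > bstart for s, e in ivs):
                hit += 1
        fracs[i] = hit / n
    out = bins.copy()
    out["direction"] = direction
    out["frequency"] = fracs
    return out


def _count_profile(sample_intervals: Mapping[str, List[Tuple[int, int]]]):
    """Step profile of contributing-sample sets over one chromosome.

    Returns a list of ``(start, end, frozenset_of_samples)`` runs covering
    the altered extent; adjacent runs are merged only when their sample sets
    are identical, and zero-coverage stretches are omitted.
    """
    points = sorted(
        {p for ivs in sample_intervals.values() for iv in ivs for p in iv}
    )
    runs = []
    for s, e in zip(points[:-1], points[1:]):
        members = frozenset(
            sample
            for sample, ivs in sample_intervals.items()
            if any(a <= s and e <= b for a, b in ivs)
        )
        if not members:
            continue
        if runs and runs[-1][1] == s and runs[-1][2] == members:
            runs[-1] = (runs[-1][0], e, members)
        else:
            runs.append((s, e, members))
    return runs


def _regions_from_runs(
    runs: List[Tuple[int, int, frozenset]],
    chrom: str,
    direction: str,
    n_group: int,
    min_count: float,
) -> List[McrRegion]:
    """Derive peak and broad MCRs from one chromosome's coverage runs."""
    regions: List[McrRegion] = []
    # group runs into maximal above-threshold blocks, allowing for genuine
    # gaps in coverage (runs list omits zero-coverage stretches)
    blocks: List[List[int]] = []
    for i, (s, e, members) in enumerate(runs):
        if len(members) >= min_count:
            contiguous = (
                blocks
                and blocks[-1]
                and runs[blocks[-1][-1]][1] == s
            )
            if contiguous:
                blocks[-1].append(i)
            else:
                blocks.append([i])
    for block in blocks:
        # peak plateaus: strict local maxima of the count profile (absent
        # neighbours count as zero coverage)
        for i in block:
            s, e, members = runs[i]
            c = len(members)
            left = runs[i - 1] if i > 0 and runs[i - 1][1] == s else None
            right = runs[i + 1] if i + 1 < len(runs) and runs[i + 1][0] == e else None
            lc = len(left[2]) if left else 0
            rc = len(right[2]) if right else 0
            if c > lc and c > rc:
                regions.append(
                    McrRegion(
                        chrom=chrom,
                        start=s,
                        end=e,
                        direction=direction,
                        frequency=c / n_group,
                        n_samples=c,
                        is_peak=True,
                    )
                )
        if len(block) > 1:
            start = runs[block[0]][0]
            end = runs[block[-1]][1]
            common = frozenset.intersection(*(runs[i][2] for i in block))
            if len(common) >= min_count:
                regions.append(
                    McrRegion(
                        chrom=chrom,
                        start=start,
                        end=end,
                        direction=direction,
                        frequency=len(common) / n_group,
                        n_samples=len(common),
                        is_peak=False,
                    )
                )
    return regions


def find_mcrs(
    calls: pd.DataFrame,
    direction: str,
    min_freq: float = DEFAULT_MIN_FREQ,
    group_samples: Optional[Sequence[str]] = None,
    cytobands: Optional[pd.DataFrame] = None,
) -> List[McrRegion]:
    """Detect minimal common regions of one direction in a sample group.

    ``min_freq`` is the recurrence threshold on the altered-sample fraction,
    in (0, 1]. When ``cytobands`` (UCSC-style table) is given, each region
    receives a band label such as ``+8q24`` or ``-1p36.32-q21.1``.
    """
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must be in (0, 1]")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    samples = (
        list(group_samples)
        if group_samples is not None
        else sorted(calls["sample"].unique())
    )
    n = len(samples)
    if n == 0:
        raise ValueError("empty sample group")
    sub = calls[calls["sample"].isin(samples)]
    per_chrom = _sample_direction_intervals(sub, direction)
    min_count = min_freq * n - 1e-9
    regions: List[McrRegion] = []
    for chrom in sorted(per_chrom):
        runs = _count_profile(per_chrom[chrom])
        regions.extend(_regions_from_runs(runs, chrom, direction, n, min_count))
    regions.sort(key=lambda r: (r.chrom, r.start, -(r.end - r.start)))
    if cytobands is not None:
        regions = [
            replace(
                r,
                cytoband_label=label_cytoband(
                    r.chrom, r.start, r.end, r.direction, cytobands
                ),
            )
            for r in regions
        ]
    return regions


def label_cytoband(
    chrom: str,
    start: int,
    end: int,
    direction: str,
    cytobands: pd.DataFrame,
) -> str:
    """Cytoband label for a region: ``+8q24`` style, hyphenated when spanning.

    ``cytobands`` follows the UCSC cytoBand layout (chrom, start, end, band
    name without the chromosome prefix, stain). Single-band regions are
    labeled by the band at the region midpoint; regions spanning several
    bands get ``firstband-lastband``. Prefix ``+`` for gains, ``-`` for
    losses.
    """
    bands = cytobands[cytobands["chrom"] == chrom]
    if bands.empty:
        raise ValueError(f"cytoband table does not cover chromosome {chrom!r}")
    chrom_num = chrom[3:] if chrom.startswith("chr") else chrom
    sign = "+" if direction == "gain" else "-"
    hit = bands[(bands["start"] < end) & (bands["end"] > start)]
    if hit.empty:
        raise ValueError(f"no cytoband overlaps {chrom}:{start}-{end}")
    names = list(hit.sort_values("start")["band"])
    if len(names) == 1:
        return f"{sign}{chrom_num}{names[0]}"
    return f"{sign}{chrom_num}{names[0]}-{names[-1]}"


def compare_cna_groups(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    bins: pd.DataFrame,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin Fisher comparison of alteration frequencies between two groups.

    For each bin and direction a two-sided Fisher exact test compares
    altered / not-altered sample counts. Returns ``(per_bin, regions)``:
    ``per_bin`` carries counts, raw p and BH q per direction; ``regions``
    merges adjacent same-direction bins with p < ``alpha`` and reports each
    merged region with its minimum p.
    """
    samples_a = sorted(calls_a["sample"].unique())
    samples_b = sorted(calls_b["sample"].unique())
    if not samples_a or not samples_b:
        raise ValueError("both groups must be non-empty")
    na, nb = len(samples_a), len(samples_b)
    pieces = []
    for direction in DIRECTIONS:
        fa = alteration_frequency(calls_a, bins, samples_a, direction)
        fb = alteration_frequency(calls_b, bins, samples_b, direction)
        ca = np.rint(fa["frequency"].to_numpy() * na).astype(int)
        cb = np.rint(fb["frequency"].to_numpy() * nb).astype(int)
        p = np.array(
            [
                fisher_exact_two_sided(a, na - a, b, nb - b)
                for a, b in zip(ca, cb)
            ]
        )
        df = bins.copy()
        df["direction"] = direction
        df["count_a"] = ca
        df["size_a"] = na
        df["count_b"] = cb
        df["size_b"] = nb
        df["p"] = p
        df["q_bh"] = benjamini_hochberg(p)
        pieces.append(df)
    per_bin = pd.concat(pieces, ignore_index=True)

    region_rows = []
    for direction in DIRECTIONS:
        df = per_bin[per_bin["direction"] == direction].reset_index(drop=True)
        current = None
        for _, row in df.iterrows():
            sig = row["p"] < alpha
            if sig and current is not None and row["chrom"] == current["chrom"] and (
                row["start"] == current["end"]
            ):
                current["end"] = row["end"]
                current["p"] = min(current["p"], row["p"])
            elif sig:
                if current is not None:
                    region_rows.append(current)
                current = {
                    "chrom": row["chrom"],
                    "start": row["start"],
                    "end": row["end"],
                    "direction": direction,
                    "p": row["p"],
                }
            else:
                if current is not None:
                    region_rows.append(current)
                    current = None
        if current is not None:
            region_rows.append(current)
    regions = pd.DataFrame(
        region_rows, columns=["chrom", "start", "end", "direction", "p"]
    )
    return per_bin, regions
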