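"""FISH scoring, subtype assignment, and immunohistochemistry calls.

Break-apart probes for MYC, BCL2 and BCL6 are scored per case over at least
100 medium-to-large cells with a 10% positivity threshold. MYC-cluster
amplification is a distinct pattern: more than 10 MYC signals per cell, seen
in at least the same 10% fraction of cells. Combining the probe calls yields
the study subtype:

* DHL  — MYC rearranged plus exactly one of BCL2/BCL6 rearranged
* THL  — MYC, BCL2 and BCL6 all rearranged
* SHL  — MYC rearranged alone
* MCAD — no MYC rearrangement but MYC-cluster amplification

IHC marker positivity uses a strict >30% tumor-cell cutoff, and the Hans
decision tree (CD10 / BCL6 / MUM1) assigns germinal-center vs non-GC origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "FishCaseResult",
    "InvalidFishCallError",
    "SUBTYPES",
    "score_breakapart",
    "detect_myc_cluster_amplification",
    "classify_subtype",
    "ihc_positive",
    "hans_cell_of_origin",
    "classify_fish_table",
]

POSITIVITY_THRESHOLD = 0.10  # fraction of cells
MIN_CELLS = 100
AMPLIFICATION_SIGNALS = 10  # strict ">" per the amplification rule

PROBES = ("MYC_BA", "BCL2_BA", "BCL6_BA", "MYC_IGH_FUSION")
SUBTYPES = ("DHL", "THL", "SHL", "MCAD", "NOT_CLASSIFIED")


class InvalidFishCallError(ValueError):
    """Raised when a probe cannot be validly called (e.g. too few cells)."""


@dataclass(frozen=True)
class FishCaseResult:
    """Per-probe scoring outcome of one case."""

    case_id: str
    probe: str
    cells_counted: int
    positive_fraction: float
    call: bool
    max_signal_fraction_gt10: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0.0 <= self.max_signal_fraction_gt10 <= 1.0:
            raise ValueError("max_signal_fraction_gt10 must be in [0, 1]")


def score_breakapart(
    cell_patterns: Sequence[str],
    threshold: float = POSITIVITY_THRESHOLD,
    min_cells: int = MIN_CELLS,
    case_id: str = "",
    probe: str = "MYC_BA",
) -> FishCaseResult:
    """Score a break-apart (or fusion) probe from per-cell patterns.

    A cell pattern of ``"split"`` (break-apart) or ``"fusion"`` (fusion probe)
    counts as positive; the case is positive when the positive-cell fraction
    reaches ``threshold``. Fewer than ``min_cells`` cells is an invalid call,
    not a negative.
    """
    if len(cell_patterns) == 0:
        raise ValueError("cell_patterns must be non-empty")
    n = len(cell_patterns)
    if n < min_cells:
        raise InvalidFishCallError(
            f"{probe}: only {n} cells counted; at least {min_cells} required"
        )
    positive = sum(1 for p in cell_patterns if p in ("split", "fusion"))
    frac = positive / n
    return FishCaseResult(
        case_id=case_id,
        probe=probe,
        cells_counted=n,
        positive_fraction=frac,
        call=frac >= threshold,
    )


def detect_myc_cluster_amplification(
    cell_signal_counts: Sequence[int],
    threshold_signals: int = AMPLIFICATION_SIGNALS,
    fraction: float = POSITIVITY_THRESHOLD,
    min_cells: int = MIN_CELLS,
) -> bool:
    """Call MYC-cluster amplification from per-cell MYC signal counts.

    True iff the fraction of cells with strictly more than
    ``threshold_signals`` MYC signals is at least ``fraction``.
    """
    n = len(cell_signal_counts)
    if n < min_cells:
        raise InvalidFishCallError(
            f"only {n} cells counted; at least {min_cells} required"
        )
    high = sum(1 for s in cell_signal_counts if s > threshold_signals)
    return high / n >= fraction


def classify_subtype(
    myc_r: bool, bcl2_r: bool, bcl6_r: bool, myc_amp: bool
) -> str:
    """Assign the study subtype from the four resolved FISH flags.

    Rearrangement takes precedence over amplification: a (hypothetical) case
    with both MYC rearrangement and cluster amplification is classified by its
    rearrangement pattern.
    """
    if myc_r:
        n_partner = int(bcl2_r) + int(bcl6_r)
        if n_partner == 2:
            return "THL"
        if n_partner == 1:
            return "DHL"
        return "SHL"
    if myc_amp:
        return "MCAD"
    return "NOT_CLASSIFIED"


def ihc_positive(percent_cells: float, threshold: float = 30.0) -> bool:
    """IHC marker positivity: strictly more than ``threshold`` % of tumor cells."""
    if not 0.0 <= percent_cells <= 100.0:
        raise ValueError(f"percent_cells must be in [0, 100], got {percent_cells}")
    return percent_cells > threshold


def hans_cell_of_origin(cd10_pos: bool, bcl6_pos: bool, mum1_pos: bool) -> str:
    """Hans immunohistochemistry decision tree (GCB vs non-GCB).

    CD10+ -> GCB; CD10- BCL6- -> non-GCB; CD10- BCL6+ MUM1- -> GCB;
    CD10- BCL6+ MUM1+ -> non-GCB.
    """
    if cd10_pos:
        return "GCB"
    if not bcl6_pos:
        return "non_GCB"
    return "non_GCB" if mum1_pos else "GCB"


def classify_fish_table(
    fish: pd.DataFrame,
    ihc: Optional[pd.DataFrame] = None,
    threshold: float = POSITIVITY_THRESHOLD,
    min_cells: int = MIN_CELLS,
) -> pd.DataFrame:
    """Score all probes of all cases and assign subtypes.

    ``fish`` is a cell-level table with columns ``case``, ``probe``,
    ``cell_index``, ``pattern``, ``signal_count`` (one row per cell per
    probe). ``ihc`` optionally provides per-case ``cd10_pct``, ``bcl6_pct``,
    ``mum1_pct`` columns for the Hans call. Returns one row per case with
    probe calls, subtype, and (when IHC is given) cell of origin.
    """
    required = {"case", "probe", "pattern", "signal_count"}
    missing = required - set(fish.columns)
    if missing:
        raise ValueError(f"fish table missing columns: {sorted(missing)}")
    rows = []
    for case_id, case_df in fish.groupby("case", sort=True):
        flags = {}
        myc_amp = False
        for probe in PROBES:
            probe_df = case_df[case_df["probe"] == probe]
            if probe_df.empty:
                flags[probe] = False
                continue
            res = score_breakapart(
                list(probe_df["pattern"]),
                threshold=threshold,
                min_cells=min_cells,
                case_id=str(case_id),
                probe=probe,
            )
            flags[probe] = res.call
            if probe == "MYC_BA":
                myc_amp = detect_myc_cluster_amplification(
                    list(probe_df["signal_count"].astype(int)),
                    fraction=threshold,
                    min_cells=min_cells,
                )
        row = {
            "case_id": case_id,
            "MYC_R": flags["MYC_BA"],
            "BCL2_R": flags["BCL2_BA"],
            "BCL6_R": flags["BCL6_BA"],
            "MYC_IGH": flags["MYC_IGH_FUSION"],
            "MYC_AMP": myc_amp,
            "subtype": classify_subtype(
                flags["MYC_BA"], flags["BCL2_BA"], flags["BCL6_BA"], myc_amp
            ),
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    if ihc is not None:
        ihc_idx = ihc.set_index("case_id")
        coo = []
        for case_id in out["case_id"]:
            if case_id in ihc_idx.index:
                r = ihc_idx.loc[case_id]
                coo.append(
                    hans_cell_of_origin(
                        ihc_positive(float(r["cd10_pct"])),
                        ihc_positive(float(r["bcl6_pct"])),
                        ihc_positive(float(r["mum1_pct"])),
                    )
                )
            else:
                coo.append("")
        out["COO"] = coo
    return out
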