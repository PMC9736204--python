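"""Interchange-format I/O, pipeline configuration, and logging.

Formats handled: per-caller VCF v4.2 (INFO keys ``GENE``, ``COSMIC``,
``LIT``, ``DMG``, ``AF``, ``CSQ``), IGV SEG, BED (0-based half-open), UCSC
cytoBand tables, tab-separated FISH / clinical / result tables, and the
truth JSON emitted by the synthetic generator. Coordinate conventions are
converted at this boundary only: VCF and SEG are 1-based (SEG inclusive),
BED and all in-memory intervals are 0-based half-open.

All writers are deterministic: stable row ordering and fixed float
formatting (6 significant digits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .variants import VariantCandidate

__all__ = [
    "VcfParseError",
    "SegParseError",
    "PipelineConfig",
    "load_config",
    "get_logger",
    "write_vcf",
    "read_vcf",
    "write_seg",
    "read_seg",
    "read_bed",
    "read_cytoband",
    "write_table",
    "read_table",
    "write_truth",
    "read_truth",
]

FLOAT_FORMAT = "%.6g"
CONFIG_SCHEMA_VERSION = 1

_log = logging.getLogger("hgblkit")


def get_logger(name: str = "hgblkit") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


class VcfParseError(ValueError):
    pass


class SegParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_INFO_HEADER = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">',
    '##INFO=<ID=COSMIC,Number=1,Type=Integer,Description="Confirmed somatic in COSMIC (0/1)">',
    '##INFO=<ID=LIT,Number=1,Type=Integer,Description="Described as somatic/driver in the literature (0/1)">',
    '##INFO=<ID=DMG,Number=1,Type=Integer,Description="Damaging verdicts among 4 predictors (0..4)">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
]


def write_vcf(
    candidates: Sequence[VariantCandidate],
    path: str,
    genome: Optional[Sequence[Tuple[str, int]]] = None,
) -> None:
    """Write one caller's calls for one sample as a VCF v4.2 text file."""
    lines = ["##fileformat=VCFv4.2"]
    if genome:
        for chrom, length in genome:
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.extend(_VCF_INFO_HEADER)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    order = {c: i for i, (c, _) in enumerate(genome)} if genome else {}
    for cand in sorted(
        candidates, key=lambda c: (order.get(c.chrom, 0), c.chrom, c.pos, c.alt)
    ):
        info = [
            f"GENE={cand.gene}",
            f"COSMIC={int(cand.cosmic_somatic)}",
            f"LIT={int(cand.literature_somatic)}",
            f"DMG={cand.damaging_votes}",
        ]
        if cand.population_af is not None:
            info.append(f"AF={FLOAT_FORMAT % cand.population_af}")
        info.append(f"CSQ={cand.consequence}")
        lines.append(
            f"{cand.chrom}\t{cand.pos}\t.\t{cand.ref}\t{cand.alt}\t.\tPASS\t"
            + ";".join(info)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(
    path: str,
    sample_id: str = "",
    caller_index: int = 0,
    caller_count: int = 1,
) -> List[VariantCandidate]:
    """Read one caller's VCF into candidate precursors.

    Multi-allelic records are decomposed into one candidate per ALT allele;
    missing INFO keys map to unknown values, not errors. Positions stay
    1-based.
    """
    out: List[VariantCandidate] = []
    try:
        vcf = VCF(path)
    except Exception as err:  # htslib reports malformed headers here
        raise VcfParseError(f"{path}: malformed VCF header ({err})") from err
    try:
        for row_num, variant in enumerate(vcf, start=1):
            info = variant.INFO
            af = info.get("AF")
            for alt in variant.ALT:
                flags = [False] * caller_count
                flags[caller_index] = True
                out.append(
                    VariantCandidate(
                        sample_id=sample_id,
                        gene=info.get("GENE") or "",
                        chrom=variant.CHROM,
                        pos=variant.POS,
                        ref=variant.REF,
                        alt=alt,
                        consequence=info.get("CSQ") or "other",
                        caller_flags=tuple(flags),
                        cosmic_somatic=bool(info.get("COSMIC") or 0),
                        literature_somatic=bool(info.get("LIT") or 0),
                        damaging_votes=int(info.get("DMG") or 0),
                        population_af=float(af) if af is not None else None,
                    )
                )
    except VcfParseError:
        raise
    except Exception as err:
        raise VcfParseError(
            f"{path}: malformed VCF record near data row {row_num} ({err})"
        ) from err
    return out


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_seg(segments: pd.DataFrame, path: str) -> None:
    """Write internal segments (0-based half-open) as IGV SEG (1-based incl.)."""
    df = segments.sort_values(["sample", "chrom", "start"], kind="stable")
    out = pd.DataFrame(
        {
            "ID": df["sample"],
            "chrom": df["chrom"],
            "loc.start": df["start"].astype(int) + 1,
            "loc.end": df["end"].astype(int),
            "num.mark": df.get("num_probes", pd.Series([0] * len(df))).astype(int),
            "seg.mean": df["value"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_seg(path: str) -> pd.DataFrame:
    """Read an IGV SEG file into internal 0-based half-open segments."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise SegParseError(f"{path}: missing SEG columns {sorted(missing)}")
    if len(df) == 0:
        return pd.DataFrame(
            columns=["sample", "chrom", "start", "end", "num_probes", "value"]
        )
    start = df["loc.start"].astype(int) - 1
    end = df["loc.end"].astype(int)
    bad = start.to_numpy() >= end.to_numpy()
    if bad.any():
        row = int(np.argmax(bad)) + 2  # header + 1-based
        raise SegParseError(f"{path}: inverted coordinates at line {row}")
    return pd.DataFrame(
        {
            "sample": df["ID"].astype(str),
            "chrom": df["chrom"].astype(str),
            "start": start,
            "end": end,
            "num_probes": df["num.mark"].astype(int),
            "value": df["seg.mean"].astype(float),
        }
    )


# ---------------------------------------------------------------------------
# BED / cytoband / tables / truth
# ---------------------------------------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file (0-based half-open); columns chrom/start/end[/name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df[cols]


def write_bed(intervals: Sequence[Tuple], path: str, chrom: str = "") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if len(iv) >= 3:
                fh.write("\t".join(str(x) for x in iv[:4]) + "\n")
            else:
                fh.write(f"{chrom}\t{iv[0]}\t{iv[1]}\n")


def read_cytoband(path: str) -> pd.DataFrame:
    """Read a UCSC cytoBand.txt table (no header, 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
    )
    return df


def write_cytoband(cytobands: pd.DataFrame, path: str) -> None:
    cytobands.to_csv(path, sep="\t", index=False, header=False)


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: Mapping[str, dict], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)


def read_truth(path: str) -> Dict[str, dict]:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved top-level pipeline configuration."""

    input_dir: str
    output_dir: str
    panel_path: str = ""
    bcl6_exons_path: str = ""
    cytoband_path: str = ""
    min_callers: int = 3
    caller_count: int = 5
    af_snp: float = 0.01
    af_likely: float = 0.001
    fish_threshold: float = 0.10
    fish_min_cells: int = 100
    gain_log2: float = 0.3
    loss_log2: float = -0.3
    min_freq: float = 0.3
    bin_size: int = 1_000_000
    alpha: float = 0.05
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def validate(self):
        if not 0 < self.min_callers <= self.caller_count:
            raise ValueError("min_callers must be in 1..caller_count")
        if not 0 < self.fish_threshold <= 1:
            raise ValueError("fish_threshold must be in (0, 1]")
        if not 0 < self.min_freq <= 1:
            raise ValueError("min_freq must be in (0, 1]")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


def load_config(path: str) -> PipelineConfig:
    """Load a YAML pipeline configuration; unknown keys warn, not fail."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        get_logger().warning("ignoring unknown config keys: %s", sorted(unknown))
    kwargs = {k: v for k, v in raw.items() if k in known}
    cfg = PipelineConfig(**kwargs)
    if cfg.schema_version != CONFIG_SCHEMA_VERSION:
        get_logger().warning(
            "config schema version %s != expected %s",
            cfg.schema_version, CONFIG_SCHEMA_VERSION,
        )
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

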