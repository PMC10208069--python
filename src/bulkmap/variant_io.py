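"""Readers and writers for the small set of formats the pipeline touches.

Dialects (deliberately minimal):

* VCF 4.2 subset: biallelic sites only, FORMAT ``GT:AD:GQ``, one ALT per
  record; multi-allelic records are skipped with a warning and counted.
* BED3 output, converting from the internal 1-based inclusive convention
  to BED's 0-based half-open at this boundary only.
* Tab-separated genotype / phenotype / panel / marker-info tables.

All writers are deterministic (stable column order, ``\\n`` line endings,
trailing newline), so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GENOTYPE_CODES, PHENOTYPES, GenomicInterval, GenotypeMatrix
from .errors import ParseError

log = logging.getLogger(__name__)

VALID_GT = ("0/0", "0/1", "1/1", "./.")


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at one site: genotype, (ref, alt) depths, GQ.

    ``ad`` and ``gq`` are ``None`` when the field is missing ('.').
    """

    gt: str = "./."
    ad: tuple | None = None
    gq: int | None = None

    def __post_init__(self):
        if self.gt not in VALID_GT:
            raise ValueError(f"invalid genotype {self.gt!r}")
        if self.ad is not None:
            if len(self.ad) != 2 or min(self.ad) < 0:
                raise ValueError(f"invalid allele depths {self.ad!r}")

    @property
    def total_depth(self) -> int:
        return 0 if self.ad is None else int(self.ad[0] + self.ad[1])

    @property
    def is_hom_ref(self) -> bool:
        return self.gt == "0/0"

    @property
    def is_hom_alt(self) -> bool:
        return self.gt == "1/1"

    @property
    def is_het(self) -> bool:
        return self.gt == "0/1"

    @property
    def is_missing(self) -> bool:
        return self.gt == "./."


@dataclass
class VariantRecord:
    """One biallelic site with per-sample GT, allele depths and GQ."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict = field(default_factory=dict)
    vid: str = "."

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SampleRoles:
    """Maps the four analysis roles onto VCF sample names."""

    parent_green: str = "parent_green"
    parent_yellow: str = "parent_yellow"
    pool_green: str = "pool_green"
    pool_yellow: str = "pool_yellow"

    def as_tuple(self):
        return (self.parent_green, self.parent_yellow,
                self.pool_green, self.pool_yellow)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_sample_field(field_str: str, keys: list, line_no: int) -> SampleCall:
    parts = field_str.split(":")
    values = dict(zip(keys, parts))
    gt = values.get("GT", "./.")
    if gt in ("./.", "."):
        gt = "./."
    else:
        gt = gt.replace("|", "/")
        alleles = sorted(gt.split("/"))
        gt = "/".join(alleles)
    if gt not in VALID_GT:
        raise ParseError(f"line {line_no}: invalid GT {values.get('GT')!r}")
    ad_raw = values.get("AD", ".")
    if ad_raw in (".", "", None):
        ad = None
    else:
        try:
            ref_d, alt_d = (int(x) for x in ad_raw.split(","))
        except ValueError:
            raise ParseError(f"line {line_no}: invalid AD {ad_raw!r}") from None
        ad = (ref_d, alt_d)
    gq_raw = values.get("GQ", ".")
    if gq_raw in (".", "", None):
        gq = None
    else:
        try:
            gq = int(gq_raw)
        except ValueError:
            raise ParseError(f"line {line_no}: invalid GQ {gq_raw!r}") from None
    return SampleCall(gt=gt, ad=ad, gq=gq)


def read_vcf(path) -> list:
    """Parse a VCF into :class:`VariantRecord` objects.

    Multi-allelic records are skipped (counted and logged); the sample set
    is taken from the ``#CHROM`` header line.
    """
    path = Path(path)
    records = []
    samples = None
    declared = set()
    n_multi = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##FORMAT=<ID="):
                    declared.add(line.split("##FORMAT=<ID=")[1].split(",")[0])
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise ParseError(f"line {line_no}: header has no samples")
                samples = cols[9:]
                missing = {"GT", "AD", "GQ"} - declared
                if missing:
                    raise ParseError(
                        f"line {line_no}: header does not declare FORMAT "
                        f"field(s) {sorted(missing)}"
                    )
                continue
            if samples is None:
                raise ParseError(f"line {line_no}: data before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise ParseError(
                    f"line {line_no}: expected {9 + len(samples)} columns, "
                    f"got {len(cols)}"
                )
            chrom, pos_s, vid, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            if "," in alt:
                n_multi += 1
                continue
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"line {line_no}: invalid POS {pos_s!r}") from None
            keys = cols[8].split(":")
            calls = {
                name: _parse_sample_field(fld, keys, line_no)
                for name, fld in zip(samples, cols[9:])
            }
            records.append(VariantRecord(chrom=chrom, pos=pos, ref=ref,
                                         alt=alt, calls=calls, vid=vid))
    if samples is None:
        raise ParseError("no #CHROM header found")
    if n_multi:
        log.warning("skipped %d multi-allelic record(s) in %s", n_multi, path)
    first = set(records[0].calls) if records else set(samples)
    for rec in records:
        if set(rec.calls) != first:
            raise ParseError(f"inconsistent sample set at {rec.chrom}:{rec.pos}")
    return records


def _format_call(call: SampleCall) -> str:
    ad = "." if call.ad is None else f"{call.ad[0]},{call.ad[1]}"
    gq = "." if call.gq is None else str(call.gq)
    return f"{call.gt}:{ad}:{gq}"


def write_vcf(records, path, sample_order=None, contig_lengths=None) -> None:
    """Write records as VCF 4.2 with FORMAT ``GT:AD:GQ``."""
    if sample_order is None:
        if not records:
            raise ValueError("sample_order required for an empty record list")
        sample_order = list(records[0].calls)
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_order),
    ]
    for rec in records:
        fields = [rec.chrom, str(rec.pos), rec.vid, rec.ref, rec.alt,
                  ".", "PASS", ".", "GT:AD:GQ"]
        fields += [_format_call(rec.calls[s]) for s in sample_order]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals, path) -> None:
    """Write intervals as BED3 (0-based half-open)."""
    lines = [f"{iv.chrom}\t{iv.start - 1}\t{iv.end}" for iv in intervals]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_bed(path) -> list:
    """Read BED3 back into 1-based inclusive :class:`GenomicInterval`."""
    intervals = []
    for line_no, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("track", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"line {line_no}: expected >= 3 BED columns")
        intervals.append(GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2])))
    return intervals


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_genotype_table(matrix: GenotypeMatrix, path) -> None:
    """TSV: ``id`` column then one single-character code column per marker."""
    lines = ["\t".join(["id"] + list(matrix.markers))]
    for i, ind in enumerate(matrix.ids):
        lines.append("\t".join([str(ind)] + list(matrix.codes[i])))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_table(path, phenotypes=None, positions=None,
                        chrom=None) -> GenotypeMatrix:
    """Read a marker-genotype TSV.

    ``phenotypes``/``positions``/``chrom`` attach side information that the
    code table itself does not carry (see :func:`read_marker_info`).
    """
    ids, rows = [], []
    markers = None
    for line_no, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if markers is None:
            if parts[0] != "id":
                raise ParseError(f"line {line_no}: first header column must be 'id'")
            markers = parts[1:]
            continue
        if len(parts) != len(markers) + 1:
            raise ParseError(
                f"line {line_no}: expected {len(markers) + 1} columns, got {len(parts)}"
            )
        for col, code in enumerate(parts[1:], start=2):
            if code not in GENOTYPE_CODES:
                raise ParseError(
                    f"line {line_no}, column {col}: unknown genotype code {code!r}"
                )
        ids.append(parts[0])
        rows.append(parts[1:])
    if markers is None:
        raise ParseError("empty genotype table")
    codes = np.array(rows, dtype="<U1") if rows else np.empty((0, len(markers)), "<U1")
    return GenotypeMatrix(ids=ids, markers=markers, codes=codes,
                          phenotypes=dict(phenotypes or {}),
                          positions=positions, chrom=chrom)


def write_phenotypes(phenotypes: dict, path) -> None:
    lines = ["id\tphenotype"]
    lines += [f"{ind}\t{ph}" for ind, ph in phenotypes.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotypes(path) -> dict:
    """Read an ``id<TAB>phenotype`` table into a dict."""
    phenotypes = {}
    for line_no, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if line_no == 1:
            if parts != ["id", "phenotype"]:
                raise ParseError("phenotype table header must be 'id\\tphenotype'")
            continue
        if len(parts) != 2:
            raise ParseError(f"line {line_no}: expected 2 columns")
        ind, ph = parts
        if ph not in PHENOTYPES:
            raise ParseError(f"line {line_no}: unknown phenotype {ph!r}")
        if ind in phenotypes:
            raise ParseError(f"line {line_no}: duplicate individual id {ind!r}")
        phenotypes[ind] = ph
    return phenotypes


def write_marker_info(markers, chroms, positions, path) -> None:
    lines = ["marker\tchrom\tpos_bp"]
    lines += [f"{m}\t{c}\t{p}" for m, c, p in zip(markers, chroms, positions)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_marker_info(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str,
                                            "pos_bp": np.int64})
    expected = ["marker", "chrom", "pos_bp"]
    if list(df.columns) != expected:
        raise ParseError(f"marker info columns must be {expected}")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    """Panel TSV: id, phenotype, insertion (present/absent)."""
    out = panel.copy()
    out["insertion"] = np.where(out["insertion"], "present", "absent")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["id", "phenotype", "insertion"]
    if list(df.columns) != expected:
        raise ParseError(f"panel columns must be {expected}")
    bad_ph = set(df["phenotype"]) - set(PHENOTYPES)
    if bad_ph:
        raise ParseError(f"unknown phenotype(s) in panel: {sorted(bad_ph)}")
    bad_ins = set(df["insertion"]) - {"present", "absent"}
    if bad_ins:
        raise ParseError(f"unknown insertion value(s): {sorted(bad_ins)}")
    df["insertion"] = df["insertion"] == "present"
    return df
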