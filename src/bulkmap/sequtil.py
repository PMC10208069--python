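"""CDS consequence analysis and qPCR relative expression.

Covers what the candidate-gene stage of the pipeline needs: translating a
coding sequence under the standard genetic code, applying an insertion
(e.g. the 15 bp diagnostic insertion whose in-frame stop truncates the
encoded protein), and computing 2^-ddCt fold changes from replicate Ct
values with a Welch t-test against the calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .errors import ParseError

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class CodingSequence:
    """A DNA coding sequence over {A, C, G, T}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT character(s) in {self.id}: {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    length_aa: int
    premature_stop: bool
    stop_codon_index: int | None   # 1-based codon index of the first stop
    starts_with_atg: bool
    in_frame: bool                 # length divisible by 3


def translate_cds(cds: CodingSequence) -> TranslationResult:
    """Translate under the standard code, stopping at the first stop codon.

    ``length_aa`` excludes the stop; ``premature_stop`` is true iff a stop
    occurs before the final complete codon. A non-ATG start or a length
    not divisible by 3 is flagged, not fatal (trailing bases are ignored).
    """
    n_codons = len(cds.seq) // 3
    trimmed = cds.seq[:3 * n_codons]
    protein_full = str(Seq(trimmed).translate())
    stop = protein_full.find("*")
    if stop == -1:
        protein, stop_index, premature = protein_full, None, False
    else:
        protein = protein_full[:stop]
        stop_index = stop + 1
        premature = stop_index < n_codons
    return TranslationResult(
        protein=protein, length_aa=len(protein), premature_stop=premature,
        stop_codon_index=stop_index,
        starts_with_atg=cds.seq.startswith("ATG"),
        in_frame=len(cds.seq) % 3 == 0,
    )


def apply_insertion(cds: CodingSequence, pos: int, insert: str) -> CodingSequence:
    """Insert ``insert`` after 1-based offset ``pos`` (0 = before the start)."""
    if not 0 <= pos <= len(cds.seq):
        raise ValueError(f"insertion offset {pos} outside 0..{len(cds.seq)}")
    if insert and (set(insert.upper()) - set("ACGT")):
        raise ValueError("insert contains non-ACGT characters")
    return CodingSequence(id=cds.id, seq=cds.seq[:pos] + insert.upper()
                          + cds.seq[pos:])


def apply_deletion(cds: CodingSequence, pos: int, length: int) -> CodingSequence:
    """Delete ``length`` bases after offset ``pos``; inverse of insertion."""
    if not 0 <= pos <= len(cds.seq) - length or length < 0:
        raise ValueError("deletion outside sequence")
    return CodingSequence(id=cds.id, seq=cds.seq[:pos] + cds.seq[pos + length:])


def synthetic_orf(length_bp: int, seed=None, rng=None) -> CodingSequence:
    """A clean random ORF: ATG, non-stop codons, one terminal TAA.

    Synthetic stand-in for a real coding sequence; ``length_bp`` must be a
    multiple of 3 and >= 9.
    """
    if length_bp % 3 or length_bp < 9:
        raise ValueError("length_bp must be a multiple of 3 and >= 9")
    if rng is None:
        rng = np.random.default_rng(seed)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in STOP_CODONS]
    n_middle = length_bp // 3 - 2
    body = "".join(rng.choice(codons, size=n_middle))
    return CodingSequence(id=f"synthetic_orf_{length_bp}bp",
                          seq="ATG" + body + "TAA")


def read_fasta(path) -> list:
    return [CodingSequence(id=rec.id, seq=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences, path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="")
               for s in sequences]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

CT_COLUMNS = ["sample", "gene", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns sample, gene ('target'/'reference'), ct.

    Replicates are successive rows of the same (sample, gene); they are
    paired by order for the per-replicate delta-Ct.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"Ct table missing column(s) {sorted(missing)}")
    bad = set(df["gene"]) - {"target", "reference"}
    if bad:
        raise ParseError(f"gene must be 'target' or 'reference', got {sorted(bad)}")
    if (df["ct"] <= 0).any():
        raise ParseError("Ct values must be > 0")
    return df


def _delta_ct(df: pd.DataFrame, sample: str) -> np.ndarray:
    sub = df[df["sample"] == sample]
    target = sub[sub["gene"] == "target"]["ct"].to_numpy()
    reference = sub[sub["gene"] == "reference"]["ct"].to_numpy()
    if len(reference) == 0:
        raise ValueError(f"sample {sample!r} has no reference-gene Ct values")
    if len(target) == 0:
        raise ValueError(f"sample {sample!r} has no target-gene Ct values")
    if len(target) != len(reference):
        raise ValueError(
            f"sample {sample!r}: {len(target)} target vs {len(reference)} "
            "reference replicates (paired by index)")
    return target - reference


def ddct_fold_change(ct: pd.DataFrame, calibrator: str,
                     pooled: bool = False) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold change relative to ``calibrator``.

    delta-Ct is computed per replicate (target minus reference, paired by
    index), ddCt as the difference of sample and calibrator mean delta-Ct.
    The p-value is a two-sided t-test of the replicate delta-Ct values
    against the calibrator's (Welch by default, pooled with
    ``pooled=True``); degenerate comparisons report p = 1.
    """
    samples = list(dict.fromkeys(ct["sample"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator {calibrator!r} not in table")
    d_cal = _delta_ct(ct, calibrator)
    rows = []
    for sample in samples:
        d = _delta_ct(ct, sample)
        ddct = d.mean() - d_cal.mean()
        fold = 2.0 ** (-ddct)
        if sample == calibrator or (np.array_equal(d, d_cal)):
            p = 1.0
        else:
            p = float(stats.ttest_ind(d, d_cal, equal_var=pooled).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append((sample, len(d), float(d.mean()), float(ddct), fold, p))
    return pd.DataFrame(rows, columns=["sample", "n_replicates",
                                       "delta_ct_mean", "ddct",
                                       "fold_change", "p_value"])
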