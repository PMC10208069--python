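"""Bulked-segregant scan statistics.

Per-site statistics compare the two phenotype pools' allele depths:

* SNP-index of a pool = depth of the yellow-parent (ALT) allele divided by
  total depth at the site;
* delta(SNP-index) = SNP-index(yellow pool) - SNP-index(green pool);
* ED^2 = squared Euclidean distance between the pools' four-base
  proportion vectors (for a biallelic site this equals twice the squared
  ALT-proportion difference).

Sites are filtered (GQ, parental homozygosity, pool depth), statistics are
averaged in 200 kb windows sliding by 100 kb, windows outside the 95%/99%
reference band of the window-mean |delta| are flagged significant, and
runs of significant windows are merged into candidate peak intervals.

The model/results pair :class:`BulkedSegregantScan` / :class:`BsaScanResults`
wraps the individual operations, which remain usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenomicInterval
from .errors import BulkmapError, UndefinedValueError
from .variant_io import SampleRoles, read_vcf

DEFAULT_ROLES = SampleRoles()

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PoolCounts:
    """Read counts for one pool at one site.

    ``ref_base``/``alt_base`` name the bases the two depths belong to; for
    InDel alleles they are pseudo-base tokens ("ref"/"alt") that still give
    a well-defined two-"base" proportion vector for ED^2.
    """

    ref_depth: int
    alt_depth: int
    label: str = ""
    ref_base: str = "ref"
    alt_base: str = "alt"

    def __post_init__(self):
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt bases must differ")

    @property
    def total(self) -> int:
        return self.ref_depth + self.alt_depth

    def proportions(self) -> dict:
        """Base -> proportion of reads; only defined for total > 0."""
        if self.total == 0:
            raise UndefinedValueError(f"zero total depth in pool {self.label!r}")
        return {self.ref_base: self.ref_depth / self.total,
                self.alt_base: self.alt_depth / self.total}


def snp_index(pool: PoolCounts) -> float:
    """Fraction of pool reads carrying the yellow-parent (ALT) allele."""
    if pool.total == 0:
        raise UndefinedValueError(f"zero total depth in pool {pool.label!r}")
    return pool.alt_depth / pool.total


def delta_snp_index(green: PoolCounts, yellow: PoolCounts) -> float:
    """SNP-index(yellow pool) minus SNP-index(green pool), in [-1, 1]."""
    return snp_index(yellow) - snp_index(green)


def ed2(green: PoolCounts, yellow: PoolCounts) -> float:
    """Squared Euclidean distance between the pools' base-proportion vectors."""
    pg, py = green.proportions(), yellow.proportions()
    return sum((py.get(b, 0.0) - pg.get(b, 0.0)) ** 2 for b in set(pg) | set(py))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

FILTER_RULES = ("low_gq", "parent_het", "parent_monomorphic", "pool_missing")


@dataclass
class FilterReport:
    """Per-rule attribution of removed sites (first failing rule wins)."""

    n_input: int = 0
    n_removed: dict = field(default_factory=lambda: {r: 0 for r in FILTER_RULES})
    n_pass: int = 0

    def check(self) -> None:
        assert self.n_input == self.n_pass + sum(self.n_removed.values())

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_pass": self.n_pass,
                "n_removed": dict(self.n_removed)}


def filter_variants(records, roles: SampleRoles = DEFAULT_ROLES,
                    gq_min: int = 50):
    """Apply the study's site filters and attribute each removal.

    Keeps sites where all four samples have GQ >= ``gq_min``, the parents
    are opposite homozygotes, and both pools have reads. Rules are checked
    in the fixed order low_gq, parent_het, parent_monomorphic, pool_missing
    and a site counts against its first failing rule.
    """
    report = FilterReport(n_input=len(records))
    passing = []
    role_names = roles.as_tuple()
    for rec in records:
        for role in role_names:
            if role not in rec.calls:
                raise BulkmapError(
                    f"sample {role!r} missing from record {rec.chrom}:{rec.pos}"
                )
        pg, py = rec.calls[roles.parent_green], rec.calls[roles.parent_yellow]
        gpool, ypool = rec.calls[roles.pool_green], rec.calls[roles.pool_yellow]
        if any(c.gq is None or c.gq < gq_min for c in (pg, py, gpool, ypool)):
            report.n_removed["low_gq"] += 1
        elif pg.is_het or py.is_het or pg.is_missing or py.is_missing:
            report.n_removed["parent_het"] += 1
        elif pg.gt == py.gt:
            report.n_removed["parent_monomorphic"] += 1
        elif gpool.total_depth == 0 or ypool.total_depth == 0:
            report.n_removed["pool_missing"] += 1
        else:
            passing.append(rec)
    report.n_pass = len(passing)
    report.check()
    return passing, report


# ---------------------------------------------------------------------------
# Per-site and per-window statistics
# ---------------------------------------------------------------------------

def _base_or_pseudo(allele: str, other: str, which: str) -> str:
    if len(allele) == 1 and allele in BASES and len(other) == 1 and other in BASES:
        return allele
    return which


def pool_counts_from_record(rec, sample: str, label: str = "") -> PoolCounts:
    call = rec.calls[sample]
    ad = call.ad if call.ad is not None else (0, 0)
    return PoolCounts(ref_depth=ad[0], alt_depth=ad[1], label=label,
                      ref_base=_base_or_pseudo(rec.ref, rec.alt, "ref"),
                      alt_base=_base_or_pseudo(rec.alt, rec.ref, "alt"))


def site_statistics(records, roles: SampleRoles = DEFAULT_ROLES) -> pd.DataFrame:
    """Per-site SNP-index, delta(SNP-index) and ED^2 for filtered records.

    Expects pre-filtered records (both pools must have reads).
    """
    rows = []
    for rec in records:
        green = pool_counts_from_record(rec, roles.pool_green, "green")
        yellow = pool_counts_from_record(rec, roles.pool_yellow, "yellow")
        idx_g, idx_y = snp_index(green), snp_index(yellow)
        rows.append((rec.chrom, rec.pos, idx_g, idx_y, idx_y - idx_g,
                     ed2(green, yellow), green.total, yellow.total))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "snp_index_green", "snp_index_yellow",
        "delta_snp_index", "ed2", "depth_green", "depth_yellow",
    ])


def sliding_windows(site_stats: pd.DataFrame, window_bp: int = 200_000,
                    step_bp: int = 100_000, min_sites: int = 1,
                    chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Window means of delta(SNP-index) and ED^2.

    Windows are [k*step + 1, k*step + window] (1-based inclusive) per
    chromosome, the last truncated at the chromosome end; windows with
    fewer than ``min_sites`` sites get null (NaN) means. Input must be
    sorted by (chrom, pos).
    """
    if window_bp <= 0 or step_bp <= 0 or step_bp > window_bp:
        raise ValueError("need 0 < step_bp <= window_bp")
    df = site_stats
    # sorted = chromosomes in contiguous blocks, positions sorted per block
    blocks = df["chrom"].to_numpy()
    starts = np.flatnonzero(np.r_[True, blocks[1:] != blocks[:-1]])
    if len(set(blocks[starts])) != len(starts):
        raise ValueError("site statistics must be sorted by (chrom, pos)")
    pos_all = df["pos"].to_numpy()
    for s, e in zip(starts, np.r_[starts[1:], len(blocks)] if len(starts) else []):
        if np.any(np.diff(pos_all[s:e]) < 0):
            raise ValueError("site statistics must be sorted by (chrom, pos)")
    chroms = (list(chrom_lengths) if chrom_lengths
              else list(dict.fromkeys(df["chrom"])))
    rows = []
    for chrom in chroms:
        sub = df[df["chrom"] == chrom]
        length = (chrom_lengths[chrom] if chrom_lengths
                  else (int(sub["pos"].max()) if len(sub) else 0))
        if length == 0:
            continue
        pos = sub["pos"].to_numpy()
        n_windows = (length - 1) // step_bp + 1
        for k in range(n_windows):
            start = k * step_bp + 1
            end = min(k * step_bp + window_bp, length)
            lo, hi = np.searchsorted(pos, [start, end + 1])
            n_sites = hi - lo
            if n_sites >= min_sites and n_sites > 0:
                mean_delta = float(sub["delta_snp_index"].iloc[lo:hi].mean())
                mean_ed2 = float(sub["ed2"].iloc[lo:hi].mean())
            else:
                mean_delta = mean_ed2 = np.nan
            rows.append((chrom, start, end, n_sites, mean_delta, mean_ed2))
    win = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                      "mean_delta", "mean_ed2"])
    win["sig95"] = False
    win["sig99"] = False
    return win


def window_site_depths(site_stats: pd.DataFrame, windows: pd.DataFrame) -> list:
    """Per-window (n_sites, 2) arrays of observed (green, yellow) depths."""
    out = []
    for _, w in windows.iterrows():
        sub = site_stats[(site_stats["chrom"] == w["chrom"])
                         & (site_stats["pos"] >= w["start"])
                         & (site_stats["pos"] <= w["end"])]
        out.append(sub[["depth_green", "depth_yellow"]].to_numpy(dtype=np.int64))
    return out


# ---------------------------------------------------------------------------
# Significance thresholds
# ---------------------------------------------------------------------------

def null_thresholds(depth_per_window, pool_size: int = 30,
                    population: str = "F2", quantiles=(0.95, 0.99),
                    n_sims: int = 2000, seed=None, rng=None) -> np.ndarray:
    """Monte-Carlo null quantiles of the window-mean |delta(SNP-index)|.

    For each simulated site, 2*pool_size F2 gametes per bulk are drawn
    without phenotype selection (B-allele count ~ Binomial(2m, 1/2)), reads
    are binomially sampled at the window's observed per-site depths, and
    the |window mean delta| quantiles are taken (linear interpolation).

    ``depth_per_window``: one array per window, shape (n_sites,) for a
    shared depth or (n_sites, 2) for (green, yellow) depths.

    Returns an array of shape (n_windows, len(quantiles)); windows with no
    sites get NaN thresholds.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    if population != "F2":
        raise ValueError(f"unsupported population {population!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    m2 = 2 * pool_size
    out = np.full((len(depth_per_window), len(quantiles)), np.nan)
    for wi, depths in enumerate(depth_per_window):
        depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
        if depths.size == 0:
            continue
        if depths.ndim == 1:
            depths = np.stack([depths, depths], axis=1)
        if np.any(depths <= 0):
            raise ValueError(f"window {wi}: zero observed depth")
        n_sites = depths.shape[0]
        f_g = rng.binomial(m2, 0.5, size=(n_sims, n_sites)) / m2
        f_y = rng.binomial(m2, 0.5, size=(n_sims, n_sites)) / m2
        idx_g = rng.binomial(depths[:, 0], f_g) / depths[:, 0]
        idx_y = rng.binomial(depths[:, 1], f_y) / depths[:, 1]
        window_mean = np.abs((idx_y - idx_g).mean(axis=1))
        out[wi] = np.quantile(window_mean, quantiles, method="linear")
    return out


def quantile_thresholds(windows: pd.DataFrame,
                        quantiles=(0.95, 0.99)) -> np.ndarray:
    """Global empirical quantiles of the observed window-mean |delta|.

    This is the "top 5% / top 1%" reading of the study's plotted
    significance lines; a causal peak occupies the upper tail, so the
    returned thresholds sit above everything unlinked.
    """
    values = windows["mean_delta"].abs().dropna().to_numpy()
    if values.size == 0:
        raise ValueError("no windows with data")
    return np.quantile(values, quantiles, method="linear")


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A run of merged significant windows."""

    interval: GenomicInterval
    peak_window: GenomicInterval
    max_mean_delta: float
    max_mean_ed2: float
    n_windows: int


def annotate_significance(windows: pd.DataFrame, thr95, thr99,
                          require_ed2: bool = False,
                          ed2_min: float = 0.5) -> pd.DataFrame:
    """Set sig95/sig99 flags comparing |mean_delta| to the thresholds.

    ``thr95``/``thr99`` may be scalars or per-window arrays. With
    ``require_ed2`` the window's mean ED^2 must also reach ``ed2_min``.
    """
    win = windows.copy()
    delta = win["mean_delta"].abs().to_numpy()
    with np.errstate(invalid="ignore"):
        sig95 = delta >= np.asarray(thr95)
        sig99 = delta >= np.asarray(thr99)
    ok = ~np.isnan(delta)
    if require_ed2:
        ok &= win["mean_ed2"].to_numpy() >= ed2_min
    win["sig95"] = sig95 & ok
    win["sig99"] = sig99 & ok
    return win


def call_peaks(windows: pd.DataFrame, thresholds=None, level: int = 99,
               require_ed2: bool = False, merge_gap_bp: int = 0) -> list:
    """Merge runs of overlapping/adjacent significant windows into peaks.

    ``thresholds`` is (thr95, thr99) (scalars or per-window arrays); when
    omitted, the sig flags already present in ``windows`` are used.
    ``level`` selects the 95 or 99 track. Significant runs separated by at
    most ``merge_gap_bp`` are additionally fused: within the linkage-decay
    scale of each other they are one association signal, not two (the
    window statistic wiggles around the threshold on the peak shoulders).
    """
    if thresholds is not None:
        windows = annotate_significance(windows, thresholds[0], thresholds[1],
                                        require_ed2=require_ed2)
    flag = {95: "sig95", 99: "sig99"}[level]
    peaks = []
    sig = windows[windows[flag]]
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        run = []
        prev_end = None
        for _, w in sub.iterrows():
            if prev_end is not None and w["start"] > prev_end + 1 + merge_gap_bp:
                peaks.append(_make_peak(chrom, run))
                run = []
            run.append(w)
            prev_end = max(prev_end or 0, int(w["end"]))
        if run:
            peaks.append(_make_peak(chrom, run))
    return peaks


def _make_peak(chrom, run) -> Peak:
    start = min(int(w["start"]) for w in run)
    end = max(int(w["end"]) for w in run)
    best = max(run, key=lambda w: w["mean_delta"])
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        peak_window=GenomicInterval(chrom, int(best["start"]), int(best["end"])),
        max_mean_delta=float(best["mean_delta"]),
        max_mean_ed2=float(max(w["mean_ed2"] for w in run)),
        n_windows=len(run),
    )


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

class BulkedSegregantScan:
    """Bulked-segregant genome scan model.

    Built from biallelic variant records carrying both parents and both
    phenotype pools; :meth:`fit` runs filtering, per-site statistics,
    window smoothing, thresholding and peak calling, returning a
    :class:`BsaScanResults`.

    Parameters
    ----------
    records : list of VariantRecord
    roles : SampleRoles
        Sample names for the two parents and two pools.
    gq_min : int
        Genotype-quality filter threshold (default 50).
    chrom_lengths : dict, optional
        Chromosome lengths in bp; defaults to the last site per chromosome.
    """

    def __init__(self, records, roles: SampleRoles = DEFAULT_ROLES,
                 gq_min: int = 50, chrom_lengths: dict | None = None):
        self.records = records
        self.roles = roles
        self.gq_min = gq_min
        self.chrom_lengths = chrom_lengths

    @classmethod
    def from_vcf(cls, path, roles: SampleRoles = DEFAULT_ROLES,
                 gq_min: int = 50, chrom_lengths: dict | None = None):
        return cls(read_vcf(path), roles=roles, gq_min=gq_min,
                   chrom_lengths=chrom_lengths)

    def fit(self, window_bp: int = 200_000, step_bp: int = 100_000,
            min_sites: int = 1, threshold_mode: str = "quantile",
            quantiles=(0.95, 0.99), n_sims: int = 2000, pool_size: int = 30,
            seed=None, require_ed2: bool = False, level: int = 99,
            merge_gap_bp: int = 2_000_000) -> "BsaScanResults":
        """Run the scan.

        ``threshold_mode="quantile"`` takes the significance thresholds as
        global empirical quantiles of the observed |window mean delta|
        (the study's "top 5% / top 1%" lines); ``"simulate"`` uses the
        per-window genotype-resampling Monte-Carlo null instead
        (:func:`null_thresholds`; needs ``seed`` for determinism).
        """
        passing, report = filter_variants(self.records, self.roles, self.gq_min)
        sites = site_statistics(passing, self.roles)
        windows = sliding_windows(sites, window_bp, step_bp, min_sites,
                                  self.chrom_lengths)
        if threshold_mode == "quantile":
            thr95, thr99 = quantile_thresholds(windows, quantiles)
        elif threshold_mode == "simulate":
            depths = window_site_depths(sites, windows)
            thr = null_thresholds(depths, pool_size=pool_size,
                                  quantiles=quantiles, n_sims=n_sims, seed=seed)
            thr95, thr99 = thr[:, 0], thr[:, 1]
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        windows = annotate_significance(windows, thr95, thr99,
                                        require_ed2=require_ed2)
        peaks = call_peaks(windows, level=level, merge_gap_bp=merge_gap_bp)
        return BsaScanResults(
            model=self, filter_report=report, sites=sites, windows=windows,
            thresholds={"mode": threshold_mode, "thr95": thr95, "thr99": thr99},
            peaks=peaks, params={
                "window_bp": window_bp, "step_bp": step_bp,
                "min_sites": min_sites, "level": level,
                "require_ed2": require_ed2, "n_sims": n_sims,
                "pool_size": pool_size, "seed": seed,
                "merge_gap_bp": merge_gap_bp,
            })


@dataclass
class BsaScanResults:
    """Fitted bulked-segregant scan: sites, windows, thresholds, peaks."""

    model: BulkedSegregantScan
    filter_report: FilterReport
    sites: pd.DataFrame
    windows: pd.DataFrame
    thresholds: dict
    peaks: list
    params: dict

    def summary(self) -> str:
        rep = self.filter_report
        lines = [
            "Bulked-segregant scan",
            "=" * 54,
            f"sites in / passing filters : {rep.n_input} / {rep.n_pass}",
        ]
        for rule, n in rep.n_removed.items():
            lines.append(f"  removed ({rule:<18s}): {n}")
        lines.append(
            f"windows ({self.params['window_bp'] // 1000} kb, "
            f"step {self.params['step_bp'] // 1000} kb)  : {len(self.windows)}"
        )
        thr95, thr99 = self.thresholds["thr95"], self.thresholds["thr99"]
        if np.ndim(thr95) == 0:
            lines.append(f"|delta| thresholds (95/99%): "
                         f"{float(thr95):.4f} / {float(thr99):.4f} "
                         f"[{self.thresholds['mode']}]")
        else:
            lines.append(f"|delta| thresholds (95/99%): per-window "
                         f"[{self.thresholds['mode']}], medians "
                         f"{np.nanmedian(thr95):.4f} / {np.nanmedian(thr99):.4f}")
        lines.append(f"called peak intervals ({self.params['level']}% level): "
                     f"{len(self.peaks)}")
        for pk in self.peaks:
            lines.append(
                f"  {pk.interval}  width {pk.interval.width_bp / 1e6:.2f} Mb  "
                f"max delta {pk.max_mean_delta:.3f}  max ED2 {pk.max_mean_ed2:.3f}"
            )
        return "\n".join(lines)

    def peak_intervals(self) -> list:
        return [pk.interval for pk in self.peaks]

    def plot(self, path=None, figsize=(10, 5)):
        from .plotting import manhattan
        return manhattan(self.windows, self.thresholds, path=path,
                         figsize=figsize)

    def save(self, out_prefix) -> dict:
        """Write per-site TSV, per-window TSV, peak BED and filter report."""
        import json
        from pathlib import Path

        from .variant_io import write_bed

        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "sites": f"{prefix}.sites.tsv",
            "windows": f"{prefix}.windows.tsv",
            "peaks": f"{prefix}.peaks.bed",
            "filter_report": f"{prefix}.filter_report.json",
        }
        self.sites.to_csv(paths["sites"], sep="\t", index=False,
                          float_format="%.6g", lineterminator="\n")
        self.windows.to_csv(paths["windows"], sep="\t", index=False,
                            float_format="%.6g", lineterminator="\n")
        write_bed(self.peak_intervals(), paths["peaks"])
        Path(paths["filter_report"]).write_text(
            json.dumps(self.filter_report.to_dict(), indent=2, sort_keys=True)
            + "\n")
        return paths
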