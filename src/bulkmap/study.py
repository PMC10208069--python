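"""Replicate-level evaluation of the scan under the study design.

Utilities to re-run the whole simulate -> scan chain many times and
collect, per replicate, the quantities a power/calibration analysis needs:
the window statistics at the causal locus, the primary called interval,
and any intervals called away from the causal chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate as sim
from .bsa import BulkedSegregantScan
from .simulate import SimConfig


def run_replicate(seed: int, config: SimConfig | None = None,
                  **fit_kwargs) -> dict:
    """One full simulate -> bulks -> pool-seq -> scan replicate.

    Returns the fitted results plus the population, keyed by stage.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(seed)
    population = sim.simulate_f2(config, rng=rng)
    green_ids, yellow_ids = sim.build_bulks(population.individuals,
                                            config.bulk_size, rng=rng)
    records = sim.sample_pool_depths(green_ids, yellow_ids, population,
                                     rng=rng)
    contigs = {c: config.chrom_length_bp for c in population.vmap.chrom_names}
    fit_kwargs.setdefault("pool_size", config.bulk_size)
    fit_kwargs.setdefault("seed", int(rng.integers(2 ** 31)))
    results = BulkedSegregantScan(records, chrom_lengths=contigs).fit(**fit_kwargs)
    return {"config": config, "population": population, "records": records,
            "results": results}


def causal_window_stats(results, config: SimConfig) -> dict:
    """Window-mean delta and ED^2 at the window containing the causal locus.

    Of the (up to window/step) windows containing the position, the one
    with the most sites is used (ties: the earlier window).
    """
    causal_chrom = f"chr{config.causal_chrom + 1}"
    win = results.windows
    containing = win[(win["chrom"] == causal_chrom)
                     & (win["start"] <= config.causal_pos_bp)
                     & (win["end"] >= config.causal_pos_bp)]
    if containing.empty:
        return {"mean_delta": np.nan, "mean_ed2": np.nan, "n_sites": 0}
    best = containing.sort_values(["n_sites", "start"],
                                  ascending=[False, True]).iloc[0]
    return {"mean_delta": float(best["mean_delta"]),
            "mean_ed2": float(best["mean_ed2"]),
            "n_sites": int(best["n_sites"])}


def replicate_metrics(seed: int, config: SimConfig | None = None,
                      **fit_kwargs) -> dict:
    """Scan one replicate and summarize it for power/calibration analysis."""
    if config is None:
        config = SimConfig()
    rep = run_replicate(seed, config, **fit_kwargs)
    results = rep["results"]
    causal_chrom = f"chr{config.causal_chrom + 1}"
    stats = causal_window_stats(results, config)
    peaks = results.peaks
    primary = max(peaks, key=lambda p: p.max_mean_delta) if peaks else None
    off_target = [p for p in peaks if p.interval.chrom != causal_chrom]
    return {
        "seed": seed,
        "causal_window_delta": stats["mean_delta"],
        "causal_window_ed2": stats["mean_ed2"],
        "n_peaks": len(peaks),
        "primary_chrom": primary.interval.chrom if primary else None,
        "primary_start": primary.interval.start if primary else None,
        "primary_end": primary.interval.end if primary else None,
        "primary_width_bp": primary.interval.width_bp if primary else None,
        "primary_contains_causal": bool(
            primary is not None
            and primary.interval.contains(causal_chrom, config.causal_pos_bp)),
        "n_off_target_peaks": len(off_target),
    }


def scan_replicates(n_replicates: int, base_seed: int = 0,
                    config: SimConfig | None = None,
                    **fit_kwargs) -> pd.DataFrame:
    """Replicate metrics for seeds base_seed .. base_seed + n - 1."""
    rows = [replicate_metrics(base_seed + i, config, **fit_kwargs)
            for i in range(n_replicates)]
    return pd.DataFrame(rows)
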