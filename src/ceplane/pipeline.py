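"""End-to-end cohort analysis: signals in, report tables out.

``analyze_cohort`` drives the full chain in memory:

1. group channels by (region, hemisphere) and apply the >= 5 patients
   per sex eligibility rule (optionally followed by age-matched
   subsampling to k patients per sex);
2. per channel, cut non-overlapping 15 s windows, build the ordinal
   pattern distribution (D in {6, 5}, tau = 1 by default) and compute the
   (H, C) plane point of every retained window;
3. per region and quantifier, pool window-level values by sex and run the
   two-sided Mann-Whitney U test; correct each (quantifier, D) family of
   region tests with BH-FDR;
4. per region and sex, compute the Welch PSD of every channel (2 s
   Hamming blocks, 1 s step, over the first 60 s so a full-length record
   contributes 59 blocks) and summarize median/IQR curves.

``run_pipeline`` wraps this with file I/O: it reads a cohort directory
(metadata CSV + NPZ bundle or EDF files) and writes CSV report tables, a
plane-point export, PSD curves, boxplot summaries and a JSON manifest.
All outputs are deterministic given the configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    MIN_PATIENTS_PER_SEX,
    RegionGroup,
    age_matched_subsample,
    age_summary,
    build_groups,
)
from .ordinal import EmbeddingConfig
from .quantifiers import QuantifierPoint, channel_quantifiers
from .records import SignalRecord
from .spectral import BandScheme, group_psd_summary, welch_psd
from .stats import bh_fdr, boxplot_summary, compare_region
from .io import read_metadata, read_signals

__all__ = ["RunConfig", "analyze_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; the defaults are the reference analysis.

    D in {6, 5}, tau = 1, 15 s windows, Welch blocks of 2 s advanced by
    1 s over the first 60 s, at least five patients per sex, alpha = 0.05,
    BH-FDR at q = 0.05.
    """

    input_dir: str | Path | None = None
    output_dir: str | Path | None = None
    D_list: tuple[int, ...] = (6, 5)
    tau: int = 1
    window_s: float = 15.0
    min_patients_per_sex: int = MIN_PATIENTS_PER_SEX
    alpha: float = 0.05
    fdr_q: float = 0.05
    age_match: bool = False
    age_match_k: int = 5
    psd_span_s: float = 60.0
    fs_expected: float | None = 200.0
    seed: int = 0
    bands: BandScheme = field(default_factory=BandScheme)


def _comparison_frame(rows: list) -> pd.DataFrame:
    columns = [
        "region", "hemisphere", "quantifier", "D",
        "mean_f", "median_f", "sd_f", "n_f",
        "mean_m", "median_m", "sd_m", "n_m",
        "U", "p_value", "h", "p_corrected", "h_corrected",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([asdict(r) for r in rows], columns=columns)


def _apply_fdr(comparisons: pd.DataFrame, q: float) -> pd.DataFrame:
    """BH correction within each (quantifier, D) family of region tests."""
    if comparisons.empty:
        return comparisons
    out = comparisons.copy()
    for (_, _), idx in out.groupby(["quantifier", "D"]).groups.items():
        adjusted, decisions = bh_fdr(out.loc[idx, "p_value"].to_numpy(), q=q)
        out.loc[idx, "p_corrected"] = adjusted
        out.loc[idx, "h_corrected"] = decisions.astype(int)
    out["h_corrected"] = out["h_corrected"].astype("Int64")
    return out


def _group_points(
    group: RegionGroup,
    by_channel: dict[str, SignalRecord],
    cfg: EmbeddingConfig,
) -> dict[str, list[QuantifierPoint]]:
    points: dict[str, list[QuantifierPoint]] = {"F": [], "M": []}
    for sex in ("F", "M"):
        for channel_id in group.channel_ids(sex):
            points[sex].extend(channel_quantifiers(by_channel[channel_id], cfg))
    return points


def analyze_cohort(
    records: list[SignalRecord],
    metadata: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis in memory; returns the report tables.

    Keys of the returned dict: ``ages``, ``comparisons``, ``fdr``,
    ``plane_points``, ``psd_curves``, ``boxplots``.  When
    ``cfg.age_match`` is set, comparisons are computed on the age-matched
    subgroups and the ``ages`` table reflects the subsample.
    """
    if cfg is None:
        cfg = RunConfig()
    by_channel = {r.channel_id: r for r in records}
    orphans = sorted(set(metadata["channel_id"].astype(str)) - set(by_channel))
    if orphans:
        raise KeyError(f"metadata rows without signals: {orphans}")

    groups = build_groups(metadata, min_patients=cfg.min_patients_per_sex)
    eligible = [g for g in groups if g.eligible]
    if not eligible:
        warnings.warn("no (region, hemisphere) group is eligible; report is empty",
                      stacklevel=2)
    if cfg.age_match:
        eligible = [
            age_matched_subsample(g, k=cfg.age_match_k, seed=cfg.seed)
            for g in eligible
        ]

    age_rows = []
    for g in groups:
        matched = next(
            (m for m in eligible if (m.region, m.hemisphere) == (g.region, g.hemisphere)),
            g,
        )
        for sex, summ in age_summary(matched if cfg.age_match else g).items():
            age_rows.append(
                {
                    "region": g.region,
                    "hemisphere": g.hemisphere,
                    "sex": sex,
                    "n": summ.n,
                    "mean_years": summ.mean_years,
                    "sd_years": summ.sd_years,
                    "eligible": g.eligible,
                }
            )
    ages = pd.DataFrame(
        age_rows,
        columns=["region", "hemisphere", "sex", "n", "mean_years", "sd_years",
                 "eligible"],
    )

    comparison_rows = []
    point_rows = []
    box_rows = []
    psd_rows = []
    for g in eligible:
        for D in cfg.D_list:
            ecfg = EmbeddingConfig(D=D, tau=cfg.tau, window_s=cfg.window_s)
            points = _group_points(g, by_channel, ecfg)
            if not points["F"] or not points["M"]:
                continue
            for sex in ("F", "M"):
                for pt in points[sex]:
                    rec = by_channel[pt.channel_id]
                    point_rows.append(
                        {
                            "channel_id": pt.channel_id,
                            "patient_id": rec.patient_id,
                            "sex": sex,
                            "region": g.region,
                            "hemisphere": g.hemisphere,
                            "D": pt.D,
                            "window_index": pt.window_index,
                            "H": pt.H,
                            "C": pt.C,
                        }
                    )
            for quantifier in ("H", "C"):
                comparison_rows.append(
                    compare_region(
                        points["F"], points["M"], quantifier,
                        alpha=cfg.alpha, region=g.region, hemisphere=g.hemisphere,
                    )
                )
                for sex in ("F", "M"):
                    values = np.array([getattr(p, quantifier) for p in points[sex]])
                    box = boxplot_summary(values)
                    box_rows.append(
                        {
                            "region": g.region, "hemisphere": g.hemisphere,
                            "sex": sex, "quantifier": quantifier, "D": D,
                            "median": box.median, "q1": box.q1, "q3": box.q3,
                            "whisker_lo": box.whisker_lo,
                            "whisker_hi": box.whisker_hi,
                            "notch_lo": box.notch_lo, "notch_hi": box.notch_hi,
                            "n_outliers": len(box.outliers), "n": box.n,
                        }
                    )

        for sex in ("F", "M"):
            estimates = []
            for channel_id in g.channel_ids(sex):
                rec = by_channel[channel_id]
                span = int(round(cfg.psd_span_s * rec.fs))
                estimates.append(
                    welch_psd(rec.data[:span], rec.fs, channel_id=channel_id)
                )
            freqs, med, q1, q3 = group_psd_summary(estimates)
            for f, m, a, b in zip(freqs, med, q1, q3):
                psd_rows.append(
                    {
                        "region": g.region, "hemisphere": g.hemisphere, "sex": sex,
                        "freq_hz": f, "median": m, "q1": a, "q3": b,
                    }
                )

    comparisons = _apply_fdr(_comparison_frame(comparison_rows), cfg.fdr_q)
    fdr = (
        comparisons[
            ["region", "hemisphere", "quantifier", "D", "p_value",
             "p_corrected", "h_corrected"]
        ].copy()
        if not comparisons.empty
        else pd.DataFrame(
            columns=["region", "hemisphere", "quantifier", "D", "p_value",
                     "p_corrected", "h_corrected"]
        )
    )
    return {
        "ages": ages,
        "comparisons": comparisons,
        "fdr": fdr,
        "plane_points": pd.DataFrame(
            point_rows,
            columns=["channel_id", "patient_id", "sex", "region", "hemisphere",
                     "D", "window_index", "H", "C"],
        ),
        "psd_curves": pd.DataFrame(
            psd_rows,
            columns=["region", "hemisphere", "sex", "freq_hz", "median", "q1", "q3"],
        ),
        "boxplots": pd.DataFrame(
            box_rows,
            columns=["region", "hemisphere", "sex", "quantifier", "D",
                     "median", "q1", "q3", "whisker_lo", "whisker_hi",
                     "notch_lo", "notch_hi", "n_outliers", "n"],
        ),
    }


_OUTPUT_FILES = {
    "ages": "age_table.csv",
    "comparisons": "comparison_table.csv",
    "fdr": "fdr_table.csv",
    "plane_points": "plane_points.csv",
    "psd_curves": "psd_curves.csv",
    "boxplots": "boxplot_summaries.csv",
}


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Read a cohort directory, run the analysis, write the report bundle.

    Writes the tables of :func:`analyze_cohort` as CSV plus
    ``manifest.json`` (configuration, package version, seed) into
    ``cfg.output_dir``, and returns the tables.
    """
    if cfg.input_dir is None or cfg.output_dir is None:
        raise ValueError("run_pipeline needs cfg.input_dir and cfg.output_dir")
    metadata = read_metadata(Path(cfg.input_dir) / "metadata.csv")
    records = read_signals(cfg.input_dir, metadata=metadata,
                           fs_expected=cfg.fs_expected)
    tables = analyze_cohort(records, metadata, cfg)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, filename in _OUTPUT_FILES.items():
        tables[key].to_csv(out / filename, index=False)
    manifest = {
        "package": "ceplane",
        "version": __version__,
        "config": {
            **{
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(cfg).items()
                if k != "bands"
            },
            "bands": {k: list(v) for k, v in cfg.bands.bands.items()},
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return tables
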