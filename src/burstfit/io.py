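"""Event-log ingestion, interevent extraction and result serialization.

Input format: delimited text with two columns (individual id, event time in
seconds), comma-, tab- or whitespace-separated, optional header.  Times are
plain seconds (integer or real); no calendar parsing.  Alternatively a
series file holds one duration per line.

Malformed lines are counted and logged with their line numbers, never
silently dropped; a file with zero valid lines is an error.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import FitConfig, fit_multiscale, series_seed
from .gof import chi_square_test, cvm_test, ks_test
from .hazard import InterEventSeries
from .simulate import EventLog

logger = logging.getLogger("burstfit")

__all__ = [
    "read_event_log",
    "write_event_log",
    "read_interevent_series",
    "intervals_from_timestamps",
    "ExtractionResult",
    "build_fit_table",
    "summarize_population",
]

_SPLIT = re.compile(r"[,\t;]|\s+")


def read_event_log(path) -> EventLog:
    """Parse a two-column (id, time-in-seconds) delimited text file.

    The delimiter (comma, tab, semicolon or whitespace) is detected per
    line; an optional header line is skipped.  Unparseable lines are
    skipped with a logged count and line numbers; zero valid lines is a
    hard error.  Output is sorted by (id, time) — out-of-order input is
    sorted with a logged notice.
    """
    ids: list[str] = []
    times: list[float] = []
    bad: list[int] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _SPLIT.split(line) if p]
            if len(parts) < 2:
                bad.append(lineno)
                continue
            try:
                t = float(parts[1])
            except ValueError:
                if lineno == 1:  # header
                    continue
                bad.append(lineno)
                continue
            if not np.isfinite(t):
                bad.append(lineno)
                continue
            ids.append(parts[0])
            times.append(t)
    if bad:
        shown = ", ".join(map(str, bad[:10]))
        logger.warning("%s: skipped %d malformed lines (lines %s%s)", path,
                       len(bad), shown, "..." if len(bad) > 10 else "")
    if not ids:
        raise ValueError(f"{path}: no valid (id, time) lines")
    table = pd.DataFrame({"id": ids, "time": times})
    if (table.groupby("id", sort=False)["time"].diff().dropna() < 0).any():
        logger.info("%s: out-of-order timestamps sorted per individual", path)
    return EventLog(table=table)


def write_event_log(log: EventLog, path, delimiter: str = ",") -> None:
    log.table.to_csv(path, sep=delimiter, index=False)


def read_interevent_series(path) -> InterEventSeries:
    """Read a one-duration-per-line series file."""
    vals = []
    bad = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals.append(float(line))
            except ValueError:
                bad.append(lineno)
    if bad:
        logger.warning("%s: skipped %d malformed lines", path, len(bad))
    if not vals:
        raise ValueError(f"{path}: no valid durations")
    return InterEventSeries(durations=np.asarray(vals))


@dataclass(frozen=True)
class ExtractionResult:
    """Interevent series per individual plus exclusion bookkeeping."""

    series: list
    n_inactive: int = 0
    n_singletons: int = 0
    n_zero_dropped: int = 0

    def active(self, min_events: int = 100) -> list:
        """Series passing the activity filter (n > min_events)."""
        return [s for s in self.series if s.n > min_events]


def intervals_from_timestamps(
    log: EventLog,
    zero_policy: str = "keep",
    jitter_resolution: float = 1.0,
    activity_threshold: int = 100,
    seed: int = 0,
) -> ExtractionResult:
    """Consecutive differences of each individual's sorted event times.

    zero_policy handles tau = 0 (same-second events): "keep" (default; the
    model's likelihood is finite at 0), "drop", or "jitter" (add uniform
    [0, resolution) noise to timestamps before differencing, seeded).
    Individuals with a single event yield no durations and are excluded
    with a logged count; individuals at or below ``activity_threshold``
    durations are merely counted as inactive (callers filter via
    :meth:`ExtractionResult.active`).
    """
    if zero_policy not in ("keep", "drop", "jitter"):
        raise ValueError("zero_policy must be keep, drop or jitter")
    rng = np.random.default_rng(seed)
    series = []
    n_singletons = 0
    n_zero_dropped = 0
    n_inactive = 0
    for uid, grp in log.table.groupby("id", sort=True):
        t = np.sort(grp["time"].to_numpy(dtype=float))
        if t.size < 2:
            n_singletons += 1
            continue
        if zero_policy == "jitter":
            t = np.sort(t + rng.uniform(0.0, jitter_resolution, size=t.size))
        d = np.diff(t)
        if zero_policy == "drop":
            nz = d > 0
            n_zero_dropped += int(np.sum(~nz))
            d = d[nz]
            if d.size == 0:
                n_singletons += 1
                continue
        s = InterEventSeries(durations=d, individual_id=str(uid))
        if s.n <= activity_threshold:
            n_inactive += 1
        series.append(s)
    if n_singletons:
        logger.info("excluded %d individuals with < 2 usable events", n_singletons)
    if n_zero_dropped:
        logger.info("dropped %d zero durations (zero_policy='drop')", n_zero_dropped)
    if n_inactive:
        logger.info("%d individuals at or below the activity threshold (%d)",
                    n_inactive, activity_threshold)
    return ExtractionResult(series=series, n_inactive=n_inactive,
                            n_singletons=n_singletons,
                            n_zero_dropped=n_zero_dropped)


def build_fit_table(
    series_list,
    fit_config: FitConfig | None = None,
    significance_level: float = 0.05,
    bootstrap: int = 0,
) -> pd.DataFrame:
    """Cohort fit table: one row per successfully fitted individual with the
    multiscale parameter estimates, log-likelihood, the three test
    statistics with p-values, and fit warnings."""
    base = fit_config or FitConfig()
    rows = []
    n_failed = 0
    for idx, s in enumerate(series_list):
        cfg = base.with_seed(series_seed(s, base.seed))
        try:
            res = fit_multiscale(s, cfg)
        except ValueError as exc:
            n_failed += 1
            logger.warning("fit failure for %s: %s", s.individual_id, exc)
            continue
        th = res.theta_hat
        row = dict(
            id=s.individual_id or f"u{idx:05d}",
            n=s.n,
            lambda0=th.lambda0,
            t0=th.t0,
            alpha=th.alpha,
            lambda_inf=th.lambda_inf,
            log_likelihood=res.log_likelihood,
            converged=res.converged,
        )
        ks = ks_test(s, th, significance_level, bootstrap=bootstrap, fit_config=cfg)
        row.update(ks_stat=ks.statistic, ks_p=ks.p_value)
        if bootstrap:
            row.update(ks_p_bootstrap=ks.p_value_bootstrap)
        try:
            chi = chi_square_test(s, th, significance_level)
            row.update(chi2_stat=chi.statistic, chi2_p=chi.p_value)
        except ValueError:
            row.update(chi2_stat=np.nan, chi2_p=np.nan)
        cvm = cvm_test(s, th, significance_level)
        row.update(cvm_stat=cvm.statistic, cvm_p=cvm.p_value,
                   warnings=";".join(res.warnings))
        rows.append(row)
    if n_failed:
        logger.warning("build_fit_table: %d individuals failed to fit", n_failed)
    return pd.DataFrame(rows)


_PARAM_SCALES = {"lambda0": "log", "t0": "log", "lambda_inf": "log", "alpha": "linear"}


def summarize_population(fit_table: pd.DataFrame, n_bins: int = 30) -> dict:
    """Per-parameter population summaries from a cohort fit table.

    For each of lambda0, t0, lambda_inf (log-spaced bins) and alpha (linear
    bins): histogram, mean, median and a histogram-peak mode estimate.
    Returns {"summary": DataFrame, "histograms": DataFrame}, both directly
    serializable as delimited tables.
    """
    if len(fit_table) < 2:
        raise ValueError("need at least 2 fitted individuals to summarize")
    srows = []
    hrows = []
    for param, scale in _PARAM_SCALES.items():
        vals = fit_table[param].to_numpy(dtype=float)
        if scale == "log":
            x = np.log10(vals)
        else:
            x = vals
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:  # zero spread: degenerate histogram around the value
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mode_center = centers[int(np.argmax(counts))]
        mode = 10.0**mode_center if scale == "log" else mode_center
        if np.ptp(vals) == 0.0:
            mode = float(vals[0])
        srows.append(dict(parameter=param, mean=float(vals.mean()),
                          median=float(np.median(vals)), mode=float(mode),
                          scale=scale))
        left = 10.0 ** edges[:-1] if scale == "log" else edges[:-1]
        right = 10.0 ** edges[1:] if scale == "log" else edges[1:]
        for bl, br, c in zip(left, right, counts):
            hrows.append(dict(parameter=param, bin_left=float(bl),
                              bin_right=float(br), count=int(c)))
    return {"summary": pd.DataFrame(srows), "histograms": pd.DataFrame(hrows)}
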