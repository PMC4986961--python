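"""Agreement between digital and manually taken measurements.

The central tool is an out-of-bag bootstrap cross-validation: in each
iteration a with-replacement sample of 82% of the paired rows fits a linear
model ``manual ~ digital (+ session)``, the rows never drawn in that sample
are predicted, and the Pearson correlation between predicted and observed
manual values is recorded.  The mean and 2.5/97.5 percentile band over the
iterations summarise how well the digital measurement stands in for the
manual one.  An optional categorical session covariate (e.g. photography
date) absorbs between-session lighting shifts, which matter for colour
traits recorded over several weeks.

A companion harness computes per-trait Pearson correlation matrices across
acquisition conditions (lighting, camera height) for the same specimens,
and the mean pairwise correlation among a set of traits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised for unusable validation inputs or a failed bootstrap run."""


@dataclass
class ValidationResult:
    """Summary of the bootstrap cross-validation."""

    mean_r: float
    ci_low: float
    ci_high: float
    n_iterations: int
    n_used: int  # iterations that produced a correlation
    n_skipped: int
    train_fraction: float
    seed: int
    per_iteration_r: np.ndarray | None = None
    per_iteration_oob_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.mean_r <= self.ci_high + 1e-12):
            raise ValueError("mean_r must lie within [ci_low, ci_high]")


def _check_input(
    manual: np.ndarray, digital: np.ndarray, session: np.ndarray | None
) -> None:
    if manual.shape != digital.shape or manual.ndim != 1:
        raise ValidationError("manual and digital must be equal-length 1-D arrays")
    if manual.size < 10:
        raise ValidationError(f"need >= 10 paired rows, got {manual.size}")
    if np.isnan(manual).any() or np.isnan(digital).any():
        raise ValidationError("paired measurements contain missing values")
    if session is not None:
        if session.shape != manual.shape:
            raise ValidationError("session labels must pair 1:1 with measurements")
        _, counts = np.unique(session, return_counts=True)
        if counts.min() < 2:
            raise ValidationError("each session needs >= 2 rows")


def bootstrap_validation(
    manual,
    digital,
    session=None,
    train_fraction: float = 0.82,
    iterations: int = 1000,
    seed: int = 0,
) -> ValidationResult:
    """Out-of-bag bootstrap correlation between digital and manual values.

    Per iteration, ``round(n * train_fraction)`` rows are drawn with
    replacement; an ordinary-least-squares fit of
    ``manual ~ 1 + digital (+ session indicators)`` on the drawn rows
    predicts the out-of-bag rows (those never drawn), and the Pearson r
    between predictions and observations is kept.  Iterations whose
    out-of-bag set has fewer than 3 rows or zero variance are skipped but
    counted; more than 10% skips aborts with an error.

    Deterministic to the last digit for a fixed seed.
    """
    manual = np.asarray(manual, dtype=np.float64)
    digital = np.asarray(digital, dtype=np.float64)
    session_arr = None if session is None else np.asarray(session)
    _check_input(manual, digital, session_arr)
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    n = manual.size
    n_draw = int(round(n * train_fraction))
    design = [np.ones(n), digital]
    if session_arr is not None:
        levels = np.unique(session_arr)
        for lev in levels[1:]:  # first level absorbed by the intercept
            design.append((session_arr == lev).astype(np.float64))
    x = np.column_stack(design)

    rng = np.random.default_rng(seed)
    rs: list[float] = []
    oob_sizes: list[int] = []
    n_skipped = 0
    for _ in range(iterations):
        idx = rng.integers(0, n, size=n_draw)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        oob_sizes.append(int(oob.size))
        if oob.size < 3:
            n_skipped += 1
            continue
        beta, *_ = np.linalg.lstsq(x[idx], manual[idx], rcond=None)
        pred = x[oob] @ beta
        obs = manual[oob]
        if np.std(pred) < 1e-12 or np.std(obs) < 1e-12:
            n_skipped += 1
            continue
        rs.append(float(np.corrcoef(pred, obs)[0, 1]))

    if n_skipped > 0.10 * iterations:
        raise ValidationError(
            f"{n_skipped}/{iterations} iterations unusable (tiny or degenerate "
            "out-of-bag sets); data too small or too uniform for the bootstrap"
        )
    arr = np.array(rs)
    return ValidationResult(
        mean_r=float(arr.mean()),
        ci_low=float(np.percentile(arr, 2.5)),
        ci_high=float(np.percentile(arr, 97.5)),
        n_iterations=iterations,
        n_used=len(rs),
        n_skipped=n_skipped,
        train_fraction=train_fraction,
        seed=seed,
        per_iteration_r=arr,
        per_iteration_oob_size=np.array(oob_sizes),
    )


def cross_condition_correlation(
    records_by_condition: dict[str, pd.DataFrame],
    traits: list[str] | None = None,
    match_on: tuple[str, ...] = ("object_index",),
) -> dict[str, pd.DataFrame]:
    """Per-trait Pearson correlation matrices across acquisition conditions.

    Every condition must contain the same specimens in the same order
    (matched on ``match_on``).  A trait that is constant within some
    condition gets NaN entries there — an undefined correlation is reported
    as missing, never as zero.
    """
    if len(records_by_condition) < 2:
        raise ValidationError("need at least two conditions")
    conditions = list(records_by_condition)
    first = records_by_condition[conditions[0]]
    keys0 = first[list(match_on)].to_numpy()
    for cond in conditions[1:]:
        tab = records_by_condition[cond]
        if len(tab) != len(first) or not (tab[list(match_on)].to_numpy() == keys0).all():
            raise ValidationError(
                f"condition {cond!r} does not contain the same specimens in the "
                f"same order as {conditions[0]!r}"
            )
    if traits is None:
        traits = [
            c
            for c in first.columns
            if c not in match_on and pd.api.types.is_numeric_dtype(first[c])
        ]
    out: dict[str, pd.DataFrame] = {}
    for trait in traits:
        mat = np.full((len(conditions), len(conditions)), np.nan)
        vals = {c: records_by_condition[c][trait].to_numpy(dtype=float) for c in conditions}
        for i, ci in enumerate(conditions):
            for j, cj in enumerate(conditions):
                if i == j:
                    mat[i, j] = 1.0
                elif np.std(vals[ci]) > 1e-12 and np.std(vals[cj]) > 1e-12:
                    mat[i, j] = np.corrcoef(vals[ci], vals[cj])[0, 1]
        out[trait] = pd.DataFrame(mat, index=conditions, columns=conditions)
    return out


def trait_correlation_summary(records: pd.DataFrame, traits: list[str]) -> float:
    """Mean Pearson correlation over the upper triangle of the trait matrix.

    Constant traits are excluded with a warning (their correlation is
    undefined).
    """
    if len(traits) < 2:
        raise ValidationError("need at least two traits")
    if len(records) < 3:
        raise ValidationError("need at least three records")
    usable = []
    for t in traits:
        if records[t].std(ddof=0) > 1e-12:
            usable.append(t)
        else:
            logger.warning("trait %r is constant; excluded from the summary", t)
    if len(usable) < 2:
        raise ValidationError("fewer than two non-constant traits")
    corr = records[usable].corr(method="pearson").to_numpy()
    iu = np.triu_indices(len(usable), k=1)
    return float(corr[iu].mean())


def load_validation_table(
    path: str | Path,
    manual_col: str,
    digital_col: str,
    session_col: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Read a paired manual/digital table from CSV or XLSX.

    Returns ``(manual, digital, session)`` ready for
    :func:`bootstrap_validation`; rows with missing values in the selected
    columns are dropped with a log message.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    cols = [manual_col, digital_col] + ([session_col] if session_col else [])
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path} lacks column(s) {missing}; has {list(frame.columns)}")
    sub = frame[cols].dropna()
    if len(sub) < len(frame):
        logger.info("dropped %d rows with missing values", len(frame) - len(sub))
    manual = sub[manual_col].to_numpy(dtype=float)
    digital = sub[digital_col].to_numpy(dtype=float)
    session = sub[session_col].to_numpy() if session_col else None
    return manual, digital, session


def expected_oob_size(n: int, n_draw: int) -> float:
    """Analytic expected out-of-bag count: ``n * (1 - 1/n)^n_draw``."""
    return n * (1.0 - 1.0 / n) ** n_draw
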