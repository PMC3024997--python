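"""NMAR sensitivity sweep: refit the EM estimator over a grid of r values.

r = 1 is the MAR reference; smaller r postulates that untested subjects are
less likely exposed given their covariates. The default grid spans strong
(r = 0.1) to weak (r = 0.7) deviations from MAR plus the MAR fit itself.
On a fixed dataset the exposure odds ratio is expected to be nonincreasing
in r; a violation is reported as a warning (it usually signals
non-convergence), never raised on user data.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace

import pandas as pd

from .cohort import CohortTable, ModelSpec
from .em import EffectEstimate, EMFit, EMSettings, effect_estimate, fit_em

logger = logging.getLogger(__name__)

DEFAULT_R_GRID = (0.1, 0.2, 0.5, 0.7, 1.0)

#: Qualitative label for the deviation from MAR at each conventional r.
DEVIATION_TAGS = {0.1: "strong", 0.2: "strong", 0.5: "moderate", 0.7: "weak", 1.0: "none (MAR)"}


def deviation_tag(r: float) -> str:
    """Qualitative deviation-from-MAR label for a sensitivity ratio."""
    if r in DEVIATION_TAGS:
        return DEVIATION_TAGS[r]
    if r < 0.35:
        return "strong"
    if r < 0.6:
        return "moderate"
    return "weak" if r < 1.0 else "none (MAR)"


@dataclass(frozen=True)
class SweepRow:
    r: float
    estimate: EffectEstimate
    converged: bool
    n_iter: int
    fit: EMFit


@dataclass(frozen=True)
class SweepResult:
    rows: tuple[SweepRow, ...]
    term: str


def r_sweep(
    table: CohortTable,
    model_spec: ModelSpec,
    r_values: tuple[float, ...] = DEFAULT_R_GRID,
    settings: EMSettings | None = None,
    term: str | None = None,
) -> SweepResult:
    """One independent EM fit per r on the grid.

    Each grid point starts from the same complete-case initialization (no
    warm starting), so results are order-invariant. Per-point
    non-convergence is carried in the row rather than raised.
    """
    r_values = tuple(r_values)
    if not r_values:
        raise ValueError("r grid must be nonempty")
    if any(not 0.0 <= r <= 1.0 for r in r_values):
        raise ValueError("r values must lie in [0, 1]")
    if any(b <= a for a, b in zip(r_values, r_values[1:])):
        raise ValueError(f"r grid must be strictly increasing, got {r_values}")
    settings = settings or EMSettings()
    term = term or model_spec.exposure

    rows = []
    for r in r_values:
        fit = fit_em(table, model_spec, replace(settings, r=r))
        rows.append(
            SweepRow(
                r=r,
                estimate=effect_estimate(fit, term),
                converged=fit.converged,
                n_iter=fit.n_iter,
                fit=fit,
            )
        )
    ors = [row.estimate.odds_ratio for row in rows]
    if any(b > a + 1e-8 for a, b in zip(ors, ors[1:])):
        logger.warning(
            "exposure OR is not nonincreasing in r (%s); check per-r convergence",
            [round(v, 4) for v in ors],
        )
    return SweepResult(rows=tuple(rows), term=term)


def sweep_frame(sweep: SweepResult) -> pd.DataFrame:
    """Sweep as a tidy DataFrame, one row per r."""
    return pd.DataFrame(
        {
            "r": [row.r for row in sweep.rows],
            "deviation_from_mar": [deviation_tag(row.r) for row in sweep.rows],
            "odds_ratio": [row.estimate.odds_ratio for row in sweep.rows],
            "ci_low": [row.estimate.ci_low for row in sweep.rows],
            "ci_high": [row.estimate.ci_high for row in sweep.rows],
            "p_value": [row.estimate.p_value for row in sweep.rows],
            "converged": [row.converged for row in sweep.rows],
            "n_iter": [row.n_iter for row in sweep.rows],
        }
    )


def sweep_report(sweep: SweepResult, fmt: str = "text") -> str:
    """Render the sweep with r columns left-to-right, estimates as rows.

    ``fmt='csv'`` emits machine-readable CSV (3-decimal numbers);
    ``fmt='text'`` an aligned table for terminals.
    """
    if not sweep.rows:
        raise ValueError("empty sweep")
    frame = sweep_frame(sweep)

    def _num(value: float) -> str:
        return f"{value:.3f}" if pd.notna(value) else "--"

    wide = pd.DataFrame(
        {
            f"r={row.r:g}": [
                deviation_tag(row.r),
                _num(row.estimate.odds_ratio),
                f"{_num(row.estimate.ci_low)}, {_num(row.estimate.ci_high)}",
                _num(row.estimate.p_value),
            ]
            for row in sweep.rows
        },
        index=["deviation from MAR", "odds ratio estimate", "95% confidence interval", "p-value"],
    )
    if fmt == "csv":
        buf = io.StringIO()
        frame.round(6).to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "text":
        return wide.to_string()
    raise ValueError(f"unknown format {fmt!r}")
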