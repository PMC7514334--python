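"""Sweeps and loop-shaped performance curves, with CSV/JSON export.

A converter with incomplete coupling (q < 1) traces a closed,
loop-shaped locus in the (efficiency, function-value) plane — the
signature of real, irreversible engines.  At q = 1 the loop degenerates
to a single-valued curve.  This module tabulates

* efficiency and entropy production against the force ratio x,
* each characteristic function against efficiency along both branches
  of the eta -> x inversion (the loop),

and serializes the results as CSV or JSON with run metadata.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import core
from .core import DriveConditions, eta_max
from .regimes import RegimeResult

__all__ = [
    "CurveSeries",
    "SweepConfig",
    "sweep_efficiency_vs_x",
    "sweep_sigma_vs_x",
    "loop_curve",
    "loop_area",
    "export_series",
    "export_regimes",
    "DEFAULT_Q_VALUES",
]

logger = logging.getLogger(__name__)

#: Default coupling grid: the classic sweep 0.2..1 plus the mitochondrial
#: preset q = 0.95 measured for oxidative phosphorylation in rat liver.
DEFAULT_Q_VALUES = (0.2, 0.4, 0.6, 0.8, 0.95, 1.0)

CSV_COLUMNS = ["function", "q", "branch", "x", "eta", "value_reduced", "value_absolute"]


def _package_version() -> str:
    try:
        return version("litconv")
    except PackageNotFoundError:  # running from a source tree
        return "0+unknown"


@dataclass(frozen=True)
class CurveSeries:
    """Ordered samples of one characteristic function at one coupling.

    Each sample is a (x, eta, reduced value) triple tagged with the
    branch it came from ("upper"/"lower" for loop curves, "x" for
    direct x-domain sweeps).
    """

    function_id: str
    q: float
    x: np.ndarray
    eta: np.ndarray
    value: np.ndarray
    branch: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.eta) == len(self.value) == len(self.branch) == n):
            raise ValueError("x, eta, value and branch must have equal length")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self, drive: DriveConditions | None = None) -> pd.DataFrame:
        """Tabulate as a DataFrame with the canonical export schema."""
        if drive is None:
            absolute = np.full(len(self), np.nan)
        elif self.function_id == "sigma":
            absolute = self.value * drive.sigma_scale
        else:
            absolute = self.value * drive.scale
        return pd.DataFrame(
            {
                "function": self.function_id,
                "q": self.q,
                "branch": list(self.branch),
                "x": self.x,
                "eta": self.eta,
                "value_reduced": self.value,
                "value_absolute": absolute,
            }
        )


@dataclass(frozen=True)
class SweepConfig:
    """Validated grid specification for a sweep run."""

    q_values: tuple[float, ...]
    grid_start: float
    grid_stop: float
    grid_count: int
    functions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.grid_count < 2:
            raise ValueError(f"grid needs >= 2 points, got {self.grid_count}")
        if not self.grid_start < self.grid_stop:
            raise ValueError(
                f"grid must be strictly increasing, got "
                f"[{self.grid_start}, {self.grid_stop}]"
            )
        for q in self.q_values:
            if not 0.0 < q <= 1.0:
                raise ValueError(f"q values must lie in (0, 1], got {q}")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_start, self.grid_stop, self.grid_count)


def _sweep(function_id: str, q: float, x_grid: np.ndarray) -> CurveSeries:
    x = np.asarray(x_grid, dtype=float)
    f = core.reduced_function(function_id)
    pole = -1.0 / q if function_id in ("efficiency", "efficient_power") else None
    if pole is not None and np.any(x == pole):
        # flag pole samples rather than dropping them silently
        ok = x != pole
        value = np.full_like(x, np.nan)
        value[ok] = f(x[ok], q)
        logger.warning(
            "%d grid point(s) hit the efficiency pole x=%.6g at q=%.3g; "
            "flagged as NaN",
            int((~ok).sum()),
            pole,
            q,
        )
    else:
        value = np.asarray(f(x, q), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        eta = np.where(
            q * x + 1.0 != 0.0, -x * (q + x) / (q * x + 1.0), np.nan
        )
    return CurveSeries(
        function_id=function_id,
        q=q,
        x=x,
        eta=eta,
        value=value,
        branch=("x",) * len(x),
        metadata={"grid": (float(x[0]), float(x[-1]), len(x)), "mode": "x-sweep"},
    )


def sweep_efficiency_vs_x(
    q_values: Iterable[float], x_grid: Sequence[float] | np.ndarray
) -> list[CurveSeries]:
    """Tabulate eta(x; q) for each coupling on a shared x grid."""
    return [_sweep("efficiency", q, np.asarray(x_grid, float)) for q in q_values]


def sweep_sigma_vs_x(
    q_values: Iterable[float], x_grid: Sequence[float] | np.ndarray
) -> list[CurveSeries]:
    """Tabulate the reduced entropy production x^2 + 2qx + 1 per coupling."""
    return [_sweep("sigma", q, np.asarray(x_grid, float)) for q in q_values]


def sweep_function_vs_x(
    function_id: str, q_values: Iterable[float], x_grid: Sequence[float] | np.ndarray
) -> list[CurveSeries]:
    """Tabulate any reduced characteristic function against x per coupling."""
    return [_sweep(function_id, q, np.asarray(x_grid, float)) for q in q_values]


def loop_curve(
    function_id: str, q: float, eta_grid: Sequence[float] | np.ndarray | int = 201
) -> CurveSeries:
    """Loop-shaped curve of one characteristic function against efficiency.

    Concatenates the lower branch (larger |x|, eta ascending) with the
    upper branch (smaller |x|, eta descending), closing the loop at the
    two zero-efficiency endpoints.  An ``eta_grid`` given as an int
    samples [0, eta_max(q)] uniformly with that many points per branch;
    an explicit grid is clipped to eta_max(q) with a logged warning.

    At q = 1 the lower quadratic root sits at the efficiency pole
    x = -1 (a spurious root, see :func:`litconv.core.x_from_eta`), so
    both branches are taken on the single physical root x = -eta and
    the loop degenerates to the single-valued curve with zero enclosed
    area.
    """
    if function_id not in core.FUNCTION_IDS:
        raise ValueError(
            f"unknown function {function_id!r}; choose from {core.FUNCTION_IDS}"
        )
    emax = eta_max(q)
    if isinstance(eta_grid, int):
        etas = np.linspace(0.0, emax, eta_grid)
    else:
        etas = np.asarray(eta_grid, dtype=float)
        if np.any(etas > emax):
            logger.warning(
                "eta grid exceeds eta_max(q=%.3g)=%.6g; clipping %d point(s)",
                q,
                emax,
                int((etas > emax).sum()),
            )
            etas = np.clip(etas, 0.0, emax)
    degenerate = q == 1.0
    xs_lower, xs_upper = [], []
    for e in etas:
        up, lo = core.x_from_eta(float(e), q)
        xs_upper.append(up)
        xs_lower.append(up if degenerate else lo)
    x_all = np.array(xs_lower + xs_upper[::-1])
    eta_all = np.concatenate([etas, etas[::-1]])
    value = np.asarray(core.reduced_function(function_id)(x_all, q), dtype=float)
    branch = ("lower",) * len(etas) + ("upper",) * len(etas)
    return CurveSeries(
        function_id=function_id,
        q=q,
        x=x_all,
        eta=eta_all,
        value=value,
        branch=branch,
        metadata={
            "grid": (0.0, float(emax), len(etas)),
            "mode": "loop",
            "eta_max": float(emax),
        },
    )


def loop_area(series: CurveSeries) -> float:
    """Shoelace area of the sampled loop polygon in the (eta, value) plane.

    Zero (up to grid resolution) for the degenerate q = 1 curve and
    strictly positive for q < 1.
    """
    e, v = series.eta, series.value
    return 0.5 * abs(float(np.sum(e * np.roll(v, -1) - np.roll(e, -1) * v)))


def _metadata_header(extra: dict | None = None) -> list[str]:
    meta = {"package_version": _package_version()}
    if extra:
        meta.update(extra)
    blob = json.dumps(meta, sort_keys=True, default=str)
    meta["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return [f"# {k} = {v}" for k, v in meta.items()]


def _series_frame(
    series: Iterable[CurveSeries], drive: DriveConditions | None
) -> pd.DataFrame:
    frames = [s.to_frame(drive) for s in series]
    if frames:
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame(columns=CSV_COLUMNS)


def export_series(
    series: Iterable[CurveSeries] | CurveSeries,
    path: str,
    fmt: str = "csv",
    drive: DriveConditions | None = None,
    config: dict | None = None,
) -> None:
    """Write curve series to CSV or JSON.

    CSV schema: ``function,q,branch,x,eta,value_reduced,value_absolute``
    (absolute column empty in reduced mode), numbers at 12 significant
    digits, preceded by comment lines carrying run metadata.  JSON
    mirrors the data model.
    """
    if isinstance(series, CurveSeries):
        series = [series]
    series = list(series)
    df = _series_frame(series, drive)
    header = _metadata_header(config)
    try:
        if fmt == "csv":
            buf = io.StringIO()
            df.to_csv(buf, index=False, float_format="%.12g", na_rep="")
            with open(path, "w") as fh:
                fh.write("\n".join(header) + "\n" + buf.getvalue())
        elif fmt == "json":
            payload = {
                "metadata": dict(
                    kv.lstrip("# ").split(" = ", 1) for kv in header
                ),
                "series": [
                    {
                        "function": s.function_id,
                        "q": s.q,
                        "samples": json.loads(
                            s.to_frame(drive)
                            .drop(columns=["function", "q"])
                            .to_json(orient="records", double_precision=12)
                        ),
                    }
                    for s in series
                ],
            }
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
        else:
            raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")
    except OSError as err:
        raise OSError(f"failed writing {fmt} output to {path!r}: {err}") from err


def export_regimes(results: Iterable[RegimeResult], path: str, fmt: str = "json") -> None:
    """Serialize regime optima (with analytic/numeric residuals) to disk."""
    rows = [
        {
            "regime": r.regime,
            "q": r.q,
            "eta_star": r.eta_star,
            "x_star": r.x_star,
            "value_star": r.value_star,
            "method": r.method,
            "residual": r.residual,
        }
        for r in results
    ]
    try:
        if fmt == "json":
            with open(path, "w") as fh:
                json.dump(
                    {"metadata": dict(
                        kv.lstrip("# ").split(" = ", 1)
                        for kv in _metadata_header()
                    ), "regimes": rows},
                    fh,
                    indent=1,
                )
        elif fmt == "csv":
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
        else:
            raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")
    except OSError as err:
        raise OSError(f"failed writing regimes to {path!r}: {err}") from err


def read_series_csv(path: str) -> pd.DataFrame:
    """Read back a CSV written by :func:`export_series`."""
    return pd.read_csv(path, comment="#")
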