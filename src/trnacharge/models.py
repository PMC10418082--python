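"""Charge-titration correction and aminoacylation-decay models.

Titration model
---------------
When intact (A) and deacylated (B) RNA are mixed at a nominal percentage ``p``
of intact RNA, the measured charge of transcript *i* deviates from the linear
mixture because deacylation depletes some tRNA species.  With the transcript's
concentration in A defined as 1 and its concentration in B as a fraction
``F_i`` of that, the predicted charge of the mixture is

    T_i(p) = (p * T_A + (100 - p) * T_B * F_i) / (p + (100 - p) * F_i)

where ``T_A`` / ``T_B`` are the replicate-averaged measured charges of the
pure intact / deacylated samples (the 100/0 and 0/100 ratios).  ``F_i`` is the
only unknown; it is fitted per transcript over the interior mixing ratios by
bound-constrained least squares with bounds [0.25, 4].

Decay model
-----------
Ester bonds of charged tRNA hydrolyse with first-order kinetics; the charge of
a group (codon or transcript) over time is modelled as

    N(t) = N0 * (1/2)^(t / t_half) + N_inf

with bounds N0 in [0, 100] %, t_half in [1, 1e5] minutes and N_inf in
[0, 3.5] % (a small floor of molecules that still present a CCA end after
full deacylation).  The value at t = 0 is N0 + N_inf; both the amplitude N0
and that t=0 charge are reported.  95% confidence intervals come from a
bootstrap that assembles each replicate time-series by drawing one replicate
value per timepoint, refitting, and taking the 2.5/97.5 percentiles.

"BFGS with bounds" is realised as a bound-constrained quasi-Newton fit
(scipy's L-BFGS-B) with a small multi-start schedule guarding against local
minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

F_BOUNDS = (0.25, 4.0)
N0_BOUNDS = (0.0, 100.0)
THALF_BOUNDS = (1.0, 1e5)
NINF_BOUNDS = (0.0, 3.5)

#: Default decay sampling design, minutes: t=0 plus 4 min .. 40 h.
DECAY_TIMEPOINTS_MIN = (0.0, 4.0, 8.0, 16.0, 32.0, 60.0, 120.0, 240.0, 480.0, 960.0, 2400.0)

#: Default titration design: percentage of intact RNA in each mixture.
TITRATION_RATIOS = (100.0, 85.0, 70.0, 55.0, 40.0, 25.0, 10.0, 0.0)

_OPT_KW = dict(method="L-BFGS-B", options={"ftol": 1e-9, "gtol": 1e-12, "maxiter": 500})


def predict_titration_charge(p, t_a, t_b, f):
    """Predicted charge (%) of a mixture with ``p`` percent intact RNA."""
    p = np.asarray(p, dtype=float)
    denom = p + (100.0 - p) * f
    if np.any(denom <= 0):
        raise ValueError("titration denominator p + (100-p)*F must be positive")
    return (p * t_a + (100.0 - p) * t_b * f) / denom


def decay_value(t, n0, t_half, n_inf):
    """First-order decay: charge (%) at time ``t`` minutes."""
    t = np.asarray(t, dtype=float)
    return n0 * 0.5 ** (t / t_half) + n_inf


@dataclass
class TitrationFit:
    """Per-transcript concentration correction factor and fit diagnostics."""

    transcript_id: str
    f: float
    rss: float
    t_a: float
    t_b: float
    converged: bool
    at_bound: bool


@dataclass
class DecayFit:
    """Decay parameters for one group, with optional bootstrap 95% CIs."""

    group_id: str
    n0: float
    t_half: float
    n_inf: float
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    ci95: dict[str, tuple[float, float]] | None = None

    @property
    def charge_at_t0(self) -> float:
        """Model charge at t=0 (amplitude plus asymptote)."""
        return self.n0 + self.n_inf


def _multistart_minimize(objective, starts, bounds):
    best = None
    for x0 in starts:
        res = minimize(objective, x0, bounds=bounds, **_OPT_KW)
        if best is None or res.fun < best.fun:
            best = res
    return best


class TitrationModel:
    """Fit per-transcript correction factors F_i from titration measurements.

    Input is a long-format table with columns ``transcript``, ``ratio_p``
    (percent intact RNA), ``replicate``, ``measured_charge`` and optionally
    ``adapter``.  The endpoint ratios (100 and 0) define T_A and T_B; the
    interior ratios, pooled over replicates, are fitted.
    """

    def __init__(self, bounds: tuple[float, float] = F_BOUNDS):
        self.bounds = bounds

    def fit(self, data: pd.DataFrame) -> "TitrationModel":
        required = {"transcript", "ratio_p", "replicate", "measured_charge"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"titration data missing columns: {sorted(missing)}")
        fits = {}
        lo, hi = self.bounds
        for tid, grp in data.groupby("transcript", sort=True):
            ends_a = grp.loc[grp.ratio_p == 100.0, "measured_charge"]
            ends_b = grp.loc[grp.ratio_p == 0.0, "measured_charge"]
            if ends_a.empty or ends_b.empty:
                raise ValueError(f"transcript {tid}: endpoint ratios 100 and 0 required")
            t_a, t_b = float(ends_a.mean()), float(ends_b.mean())
            interior = grp[(grp.ratio_p != 100.0) & (grp.ratio_p != 0.0)]
            if interior.empty:
                raise ValueError(f"transcript {tid}: at least one interior ratio required")
            p = interior.ratio_p.to_numpy(float)
            y = interior.measured_charge.to_numpy(float)

            def objective(x, p=p, y=y, t_a=t_a, t_b=t_b):
                pred = predict_titration_charge(p, t_a, t_b, x[0])
                return float(np.sum((pred - y) ** 2))

            mid = np.sqrt(lo * hi)
            starts = [[1.0], [mid * 0.5], [min(hi, mid * 2.0)]]
            res = _multistart_minimize(objective, starts, [self.bounds])
            fhat = float(np.clip(res.x[0], lo, hi))
            fits[tid] = TitrationFit(
                transcript_id=str(tid),
                f=fhat,
                rss=float(res.fun),
                t_a=t_a,
                t_b=t_b,
                converged=bool(res.success),
                at_bound=bool(np.isclose(fhat, lo) or np.isclose(fhat, hi)),
            )
        self.fits_ = fits
        self.data_ = data
        return self

    def predict(self, transcript: str, p) -> np.ndarray:
        fit = self.fits_[transcript]
        return predict_titration_charge(p, fit.t_a, fit.t_b, fit.f)

    def error_report(self, grouping: str = "adapter") -> pd.DataFrame:
        """Binned measured-minus-predicted errors (percentage points).

        ``grouping`` is a column of the input table (``adapter``, ``ratio_p``,
        ``replicate``...).  Interior-ratio measurements only; bins partition
        them, so bin counts sum to the number of interior measurements.
        """
        data = self.data_
        if grouping not in data.columns:
            raise ValueError(f"grouping column {grouping!r} not in titration data")
        interior = data[(data.ratio_p != 100.0) & (data.ratio_p != 0.0)].copy()
        pred = np.array(
            [
                self.predict(t, p)
                for t, p in zip(interior.transcript, interior.ratio_p)
            ],
            dtype=float,
        )
        interior["error_pp"] = interior.measured_charge.to_numpy(float) - pred
        out = (
            interior.groupby(grouping)["error_pp"]
            .agg(["count", "median", "mean", "std"])
            .reset_index()
            .rename(columns={grouping: "bin"})
        )
        out["grouping"] = grouping
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transcript": f.transcript_id,
                "F": f.f,
                "rss": f.rss,
                "T_A": f.t_a,
                "T_B": f.t_b,
                "converged": f.converged,
                "at_bound": f.at_bound,
            }
            for f in self.fits_.values()
        ]
        return pd.DataFrame(rows)


def fit_correction_factors(data: pd.DataFrame) -> dict[str, TitrationFit]:
    """Functional wrapper over :class:`TitrationModel`."""
    return TitrationModel().fit(data).fits_


class DecayModel:
    """Fit the three-parameter first-order decay to charge time-series.

    Input is a long-format table with columns ``group``, ``time_min``,
    ``replicate``, ``charge``.  The point estimate pools all timepoints and
    replicates; bootstrap CIs resample one replicate per timepoint.
    """

    def __init__(self, n_boot: int = 1000, seed: int | None = None):
        self.n_boot = n_boot
        self.seed = seed

    # -- single-series fitting ------------------------------------------------
    @staticmethod
    def _fit_series(t: np.ndarray, y: np.ndarray, x0: np.ndarray | None = None):
        bounds = [N0_BOUNDS, THALF_BOUNDS, NINF_BOUNDS]

        def objective(x):
            return float(np.sum((decay_value(t, *x) - y) ** 2))

        if x0 is not None:
            return minimize(objective, x0, bounds=bounds, **_OPT_KW)

        order = np.argsort(t)
        t_sorted, y_sorted = t[order], y[order]
        n0_init = float(np.clip(np.mean(y_sorted[t_sorted == t_sorted[0]]), *N0_BOUNDS))
        ninf_init = float(np.clip(np.mean(y_sorted[t_sorted == t_sorted[-1]]), *NINF_BOUNDS))
        halfway = ninf_init + (n0_init - ninf_init) / 2.0
        below = t_sorted[y_sorted <= halfway]
        if below.size and below.max() > 0:
            thalf_init = float(np.clip(below.min() if below.min() > 0 else 1.0, *THALF_BOUNDS))
        else:
            pos = t_sorted[t_sorted > 0]
            thalf_init = float(np.exp(np.mean(np.log(pos)))) if pos.size else 60.0
        starts = [
            np.array([n0_init, thalf_init, ninf_init]),
            np.array([50.0, np.sqrt(THALF_BOUNDS[0] * THALF_BOUNDS[1]), 1.75]),
            np.array([n0_init, max(1.0, thalf_init / 10.0), ninf_init]),
        ]
        return _multistart_minimize(lambda x: objective(x), starts, bounds)

    def fit(self, series: pd.DataFrame) -> "DecayModel":
        required = {"group", "time_min", "replicate", "charge"}
        missing = required - set(series.columns)
        if missing:
            raise ValueError(f"decay series missing columns: {sorted(missing)}")
        fits = {}
        rng = np.random.default_rng(self.seed)
        for gid, grp in series.groupby("group", sort=True):
            t = grp.time_min.to_numpy(float)
            y = grp.charge.to_numpy(float)
            if np.unique(t).size < 3:
                raise ValueError(f"group {gid}: at least 3 distinct timepoints required")
            res = self._fit_series(t, y)
            n0, t_half, n_inf = (float(v) for v in res.x)
            flags = []
            if not res.success:
                flags.append("non_converged")
            for val, bnds, name in (
                (t_half, THALF_BOUNDS, "t_half"),
                (n_inf, NINF_BOUNDS, "n_inf"),
            ):
                if np.isclose(val, bnds[0]) or np.isclose(val, bnds[1]):
                    flags.append(f"{name}_at_bound")
            fit = DecayFit(
                group_id=str(gid),
                n0=n0,
                t_half=t_half,
                n_inf=n_inf,
                rss=float(res.fun),
                converged=bool(res.success),
                flags=flags,
            )
            if self.n_boot > 0:
                fit.ci95 = self._bootstrap_ci(grp, res.x, rng)
            fits[gid] = fit
        self.fits_ = fits
        return self

    def _bootstrap_ci(self, grp: pd.DataFrame, x_point: np.ndarray, rng) -> dict:
        """Bootstrap: one replicate value drawn per timepoint, refit, percentiles."""
        by_time = {
            t: sub.charge.to_numpy(float) for t, sub in grp.groupby("time_min")
        }
        times = np.array(sorted(by_time), dtype=float)
        pools = [by_time[t] for t in times]
        params = np.empty((self.n_boot, 3))
        for b in range(self.n_boot):
            y = np.array([pool[rng.integers(pool.size)] for pool in pools])
            res = self._fit_series(times, y, x0=x_point)
            params[b] = res.x
        lo, hi = np.percentile(params, [2.5, 97.5], axis=0)
        names = ("n0", "t_half", "n_inf")
        return {name: (float(lo[k]), float(hi[k])) for k, name in enumerate(names)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits_.values():
            row = {
                "group": f.group_id,
                "N0": f.n0,
                "t_half_min": f.t_half,
                "N_inf": f.n_inf,
                "charge_t0": f.charge_at_t0,
                "rss": f.rss,
                "flags": ";".join(f.flags),
            }
            if f.ci95:
                for name, (lo, hi) in f.ci95.items():
                    row[f"{name}_ci_low"] = lo
                    row[f"{name}_ci_high"] = hi
            rows.append(row)
        return pd.DataFrame(rows)


def fit_decay(series: pd.DataFrame, n_boot: int = 0, seed: int | None = None) -> dict[str, DecayFit]:
    """Functional wrapper over :class:`DecayModel`."""
    return DecayModel(n_boot=n_boot, seed=seed).fit(series).fits_


def bootstrap_decay_ci(series: pd.DataFrame, n_boot: int = 1000, seed: int | None = None) -> dict[str, dict]:
    """Bootstrap 95% CIs for every group in ``series``."""
    model = DecayModel(n_boot=n_boot, seed=seed).fit(series)
    return {gid: f.ci95 for gid, f in model.fits_.items()}
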