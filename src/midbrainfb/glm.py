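"""First-level GLMs: design construction, OLS fitting, contrasts.

Design variants mirror the analysis stages:

* block design — one HRF-convolved boxcar per regulation condition plus
  nuisance regressors (first-5-TR indicator, 6 motion, 6 PCA), fifteen
  columns in total;
* TD design — per-TR event regressors for each condition plus parametric
  modulators carrying the collapsed temporal-difference trace (backward
  difference of the SN/VTA series), mean-centered within condition;
* linear-time design — a linear (or reversed) per-TR modulator, the
  sensitization/desensitization control;
* MID design — cue-onset regressors per cue type plus reward-magnitude
  modulators for the small and large ranges, mean-centered within cue type;
* PPI design — psychological (condition) regressors, the physiological seed
  series, and per-condition interaction columns (centered condition
  indicator x centered seed), formed in the measured-signal domain.

Estimation is ordinary least squares with an internal intercept (the paper's
fifteen regressors carry no constant; the intercept absorbs the raw-signal
offset without entering any contrast).  Optional AR(1) prewhitening is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import IMAGINE, REST, MIDTrialSpec, RunDesign
from .preprocess import NuisanceSet
from .simulate import hrf_kernel

INTERCEPT = "const"


class GLMError(ValueError):
    pass


class RankError(GLMError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; suspect columns: {self.columns}")


@dataclass
class DesignMatrix:
    frame: pd.DataFrame
    run_id: str = ""

    def __post_init__(self):
        if self.frame.columns.duplicated().any():
            raise GLMError("duplicate column names in design matrix")

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def columns(self):
        return list(self.frame.columns)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class GLMFit:
    betas: pd.Series
    residual_variance: float
    dof: int
    nobs: int
    xtx_inv: np.ndarray
    design: DesignMatrix
    contrasts: dict = field(default_factory=dict)

    def beta(self, name: str) -> float:
        return float(self.betas[name])


# ---------------------------------------------------------------------------
# design construction helpers


def _boxcar(run: RunDesign, condition: str) -> np.ndarray:
    ind = np.zeros(run.n_volumes)
    found = False
    for blk in run.condition_blocks(condition):
        lo = int(round(blk.onset / run.tr))
        hi = int(round(blk.end / run.tr))
        ind[lo:hi] = 1.0
        found = True
    if not found:
        raise GLMError(f"run has no {condition} blocks (malformed design)")
    return ind


def _convolve(series: np.ndarray, tr: float) -> np.ndarray:
    return np.convolve(series, hrf_kernel(tr))[: series.size]


def _check_nuisance(nuisance: NuisanceSet, n: int) -> None:
    if nuisance.n_volumes != n:
        raise GLMError("nuisance series length does not match the run")


def _nuisance_columns(nuisance: NuisanceSet) -> dict[str, np.ndarray]:
    cols = {"initial_volumes": nuisance.initial_volumes}
    for i, m in enumerate(nuisance.motion):
        cols[f"motion_{i}"] = m
    for i, comp in enumerate(nuisance.pca_components, start=1):
        cols[f"pca_{i}"] = comp
    return cols


def build_block_design(run: RunDesign, nuisance: NuisanceSet) -> DesignMatrix:
    """Block design: 2 condition boxcars (HRF-convolved) + 13 nuisance
    regressors = 15 columns."""
    _check_nuisance(nuisance, run.n_volumes)
    cols = {
        "imagine": _convolve(_boxcar(run, IMAGINE), run.tr),
        "rest": _convolve(_boxcar(run, REST), run.tr),
    }
    cols.update(_nuisance_columns(nuisance))
    return DesignMatrix(pd.DataFrame(cols), run_id=run.run_type)


def _event_sticks(run: RunDesign, condition: str,
                  modulator: np.ndarray | None = None) -> np.ndarray:
    """Per-TR event regressor: unit sticks at every volume of the condition,
    optionally scaled by a (mean-centered within condition) modulator, then
    HRF-convolved."""
    ind = _boxcar(run, condition)
    sticks = ind.copy()
    if modulator is not None:
        mod = np.asarray(modulator, dtype=float).copy()
        sel = ind > 0
        mod_sel = mod[sel] - mod[sel].mean()
        sticks = np.zeros_like(ind)
        sticks[sel] = mod_sel
    return _convolve(sticks, run.tr)


def td_trace(snvta: np.ndarray) -> np.ndarray:
    """Collapsed TD trace: one-volume backward difference of the SN/VTA
    series; the first volume of a run gets 0."""
    snvta = np.asarray(snvta, dtype=float)
    delta = np.zeros_like(snvta)
    delta[1:] = np.diff(snvta)
    return delta


def build_td_design(run: RunDesign, snvta: np.ndarray,
                    nuisance: NuisanceSet) -> DesignMatrix:
    """TD design: per-TR event regressors for IMAGINE_REWARD and REST, each
    with a parametric modulator carrying the collapsed TD trace."""
    snvta = np.asarray(snvta, dtype=float)
    if snvta.size != run.n_volumes:
        raise GLMError("SN/VTA series length does not match the run")
    _check_nuisance(nuisance, run.n_volumes)
    delta = td_trace(snvta)
    cols = {
        "imagine_events": _event_sticks(run, IMAGINE),
        "rest_events": _event_sticks(run, REST),
        "imagine_td": _event_sticks(run, IMAGINE, delta),
        "rest_td": _event_sticks(run, REST, delta),
    }
    cols.update(_nuisance_columns(nuisance))
    return DesignMatrix(pd.DataFrame(cols), run_id=run.run_type)


def build_linear_time_design(run: RunDesign, direction: str,
                             nuisance: NuisanceSet) -> DesignMatrix:
    """Linear-time control design: per-TR events with a linear (increase) or
    reversed-linear (decrease) mean-centered modulator."""
    if direction not in ("increase", "decrease"):
        raise GLMError(f"direction must be increase/decrease, got {direction!r}")
    _check_nuisance(nuisance, run.n_volumes)
    ramp = np.arange(run.n_volumes, dtype=float)
    if direction == "decrease":
        ramp = ramp[::-1].copy()
    task = _boxcar(run, IMAGINE) + _boxcar(run, REST)
    sel = task > 0
    sticks = np.zeros(run.n_volumes)
    sticks[sel] = ramp[sel] - ramp[sel].mean()
    cols = {
        "task_events": _convolve(task, run.tr),
        "linear_mod": _convolve(sticks, run.tr),
    }
    cols.update(_nuisance_columns(nuisance))
    return DesignMatrix(pd.DataFrame(cols), run_id=run.run_type)


def build_mid_design(trials: list[MIDTrialSpec], n_volumes: int, tr: float,
                     nuisance: NuisanceSet) -> DesignMatrix:
    """MID design: cue-onset regressors per cue type plus reward-magnitude
    parametric modulators (mean-centered within cue type) for small and
    large cues."""
    _check_nuisance(nuisance, n_volumes)
    cols: dict[str, np.ndarray] = {}
    for cue in ("large", "small", "none"):
        sticks = np.zeros(n_volumes)
        onsets = []
        for t in trials:
            if t.cue_type != cue:
                continue
            vol = int(round(t.cue_onset / tr))
            if vol >= n_volumes:
                raise GLMError("trial outside the run")
            onsets.append((vol, t.magnitude))
            sticks[vol] += 1.0
        cols[f"cue_{cue}"] = _convolve(sticks, tr)
        if cue in ("large", "small"):
            mags = np.array([m for _, m in onsets])
            mod = np.zeros(n_volumes)
            for (vol, m), mc in zip(onsets, mags - mags.mean()):
                mod[vol] += mc
            cols[f"mod_{cue}"] = _convolve(mod, tr)
    cols.update(_nuisance_columns(nuisance))
    return DesignMatrix(pd.DataFrame(cols), run_id="mid")


def build_ppi_design(seed_series: np.ndarray, run: RunDesign,
                     nuisance: NuisanceSet) -> DesignMatrix:
    """gPPI-style design: psychological condition regressors, the
    physiological seed series, and per-condition interaction columns
    (centered condition indicator x centered seed), in the measured-signal
    domain (no deconvolution)."""
    seed = np.asarray(seed_series, dtype=float)
    if seed.size != run.n_volumes:
        raise GLMError("seed series length does not match the run")
    _check_nuisance(nuisance, run.n_volumes)
    seed_c = seed - seed.mean()
    cols = {
        "imagine": _convolve(_boxcar(run, IMAGINE), run.tr),
        "rest": _convolve(_boxcar(run, REST), run.tr),
        "seed": seed_c,
    }
    for name, cond in (("ppi_imagine", IMAGINE), ("ppi_rest", REST)):
        ind = _boxcar(run, cond)
        cols[name] = (ind - ind.mean()) * seed_c
    cols.update(_nuisance_columns(nuisance))
    return DesignMatrix(pd.DataFrame(cols), run_id=run.run_type)


# ---------------------------------------------------------------------------
# estimation


def _rank_deficient_columns(x: np.ndarray, names) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    bad = piv[np.where(diag < tol)[0]] if diag.size else []
    return [names[i] for i in np.atleast_1d(bad)]


def fit_ols(design: DesignMatrix, y: np.ndarray, *, add_intercept: bool = True,
            prewhiten: bool = False) -> GLMFit:
    """Ordinary least squares fit of a region series on a design matrix.

    dof = n - rank(X); contrast t statistics use the pooled residual
    variance.  With ``prewhiten=True`` a single Cochrane-Orcutt pass removes
    the residual lag-1 autocorrelation before the final fit.
    """
    y = np.asarray(y, dtype=float)
    frame = design.frame
    if y.size != len(frame):
        raise GLMError("response length does not match the design")
    if add_intercept:
        frame = frame.copy()
        frame[INTERCEPT] = 1.0
    names = list(frame.columns)
    x = frame.to_numpy(float)
    n, p = x.shape
    if n <= p:
        raise GLMError("more regressors than volumes")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise RankError(_rank_deficient_columns(x, names))

    def _solve(xm, ym):
        beta, _, _, _ = np.linalg.lstsq(xm, ym, rcond=None)
        resid = ym - xm @ beta
        return beta, resid

    beta, resid = _solve(x, y)
    if prewhiten:
        phi = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
        phi = float(np.clip(phi, -0.99, 0.99))
        xw = x.copy()
        yw = y.copy()
        xw[1:] = x[1:] - phi * x[:-1]
        yw[1:] = y[1:] - phi * y[:-1]
        scale = np.sqrt(1.0 - phi ** 2)
        xw[0] *= scale
        yw[0] *= scale
        x, y = xw, yw
        beta, resid = _solve(x, y)
    dof = n - rank
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    return GLMFit(betas=pd.Series(beta, index=names), residual_variance=sigma2,
                  dof=dof, nobs=n, xtx_inv=xtx_inv,
                  design=DesignMatrix(frame, design.run_id))


def contrast_vector(fit: GLMFit, weights) -> np.ndarray:
    names = list(fit.betas.index)
    if isinstance(weights, dict):
        unknown = set(weights) - set(names)
        if unknown:
            raise GLMError(f"unknown contrast columns: {sorted(unknown)}")
        return np.array([float(weights.get(n, 0.0)) for n in names])
    c = np.asarray(weights, dtype=float)
    if c.size == len(names) - (INTERCEPT in names):
        # weights given for the named regressors only; intercept weight 0
        c = np.append(c, 0.0) if INTERCEPT in names else c
    if c.size != len(names):
        raise GLMError("contrast weight length does not match the design")
    return c


def run_contrast(fit: GLMFit, weights, name: str | None = None) -> dict:
    """Contrast estimate, t statistic and two-sided p for c'beta."""
    c = contrast_vector(fit, weights)
    est = float(c @ fit.betas.to_numpy())
    var = float(fit.residual_variance * c @ fit.xtx_inv @ c)
    t = est / np.sqrt(var) if var > 0 else 0.0
    p = 2.0 * sps.t.sf(abs(t), fit.dof) if var > 0 else 1.0
    result = {"estimate": est, "t": float(t), "p": float(p), "dof": fit.dof}
    if name:
        fit.contrasts[name] = result
    return result


def imagine_minus_rest(fit: GLMFit) -> dict:
    """The IMAGINE_REWARD - REST contrast on a block-design fit."""
    return run_contrast(fit, {"imagine": 1.0, "rest": -1.0},
                        name="imagine_minus_rest")
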