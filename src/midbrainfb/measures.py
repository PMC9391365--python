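"""Subject-level summary statistics: DRT, training slope, TD slope, PPI, MID.

The degree of regulation transfer (DRT) quantifies how much better a subject
sustains the IMAGINE_REWARD - REST difference after training than before:

    DRT = (IMAGINE_transfer - REST_transfer) - (IMAGINE_baseline - REST_baseline)

For the midbrain it is computed directly from condition means of the
percent-signal-change-normalized SN/VTA series (both runs are feedback-free
by construction); for any other region from the difference of the two runs'
block-design contrast estimates.  The training slope is the second minus the
first training run's IMAGINE - REST contrast; the TD slope is the same
difference for the dlPFC temporal-difference modulator beta; the PPI
estimate summarizes the IMAGINE-specific dlPFC-seed interaction on the
SN/VTA during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import IMAGINE, REST, RunDesign, labels_per_volume
from .glm import (GLMFit, build_block_design, build_mid_design,
                  build_ppi_design, build_td_design, fit_ols,
                  imagine_minus_rest, run_contrast)
from .preprocess import nuisance_for_run

#: default hemodynamic label shift for condition-mean extraction (seconds)
DEFAULT_HEMODYNAMIC_SHIFT = 4.0


class MeasureError(ValueError):
    pass


@dataclass
class DRTResult:
    subject_id: str
    midbrain_drt: float
    components: dict = field(default_factory=dict)

    def check(self) -> bool:
        c = self.components
        recomputed = ((c["imagine_transfer"] - c["rest_transfer"])
                      - (c["imagine_baseline"] - c["rest_baseline"]))
        return bool(np.isclose(recomputed, self.midbrain_drt))


@dataclass
class SubjectSummary:
    subject_id: str
    arm: str
    study_id: str
    midbrain_drt: float = np.nan
    training_slope: float = np.nan
    td_slope: float = np.nan
    ppi_estimate: float = np.nan
    dlpfc_drt: float = np.nan
    control_drt: float = np.nan
    mid_sensitivity_beta: float = np.nan
    mid_adaptive_beta: float = np.nan

    def as_row(self) -> dict:
        return dict(self.__dict__)


def psc_normalize(series: np.ndarray) -> np.ndarray:
    """Per-run percent signal change: 100 * (x - mean) / mean."""
    x = np.asarray(series, dtype=float)
    m = x.mean()
    if m == 0:
        raise MeasureError("cannot PSC-normalize a zero-mean series")
    return 100.0 * (x - m) / m


def condition_means(series: np.ndarray, run: RunDesign,
                    hemodynamic_shift: float) -> dict[str, float]:
    labels = labels_per_volume(run, hemodynamic_shift)
    x = np.asarray(series, dtype=float)
    out = {}
    for cond in (IMAGINE, REST):
        sel = labels == cond
        if not sel.any():
            raise MeasureError(f"no {cond} volumes after shift")
        out[cond] = float(x[sel].mean())
    return out


def compute_drt(baseline_series, baseline_run: RunDesign, transfer_series,
                transfer_run: RunDesign,
                hemodynamic_shift: float = DEFAULT_HEMODYNAMIC_SHIFT,
                subject_id: str = "", normalize: str = "psc") -> DRTResult:
    """Midbrain DRT from condition means of the two feedback-free runs.

    ``normalize='psc'`` (default) puts both runs on a percent-signal-change
    scale before averaging; ``'center'`` only removes the run mean, which
    makes the statistic exactly invariant to adding a constant to a run.
    """
    for run in (baseline_run, transfer_run):
        if run.feedback_enabled:
            raise MeasureError(
                "DRT is defined on feedback-free runs only; got a training run")
    if normalize == "psc":
        norm = psc_normalize
    elif normalize == "center":
        norm = lambda x: np.asarray(x, dtype=float) - np.mean(x)
    else:
        raise MeasureError(f"unknown normalization {normalize!r}")
    base = condition_means(norm(baseline_series), baseline_run,
                           hemodynamic_shift)
    trans = condition_means(norm(transfer_series), transfer_run,
                            hemodynamic_shift)
    drt = (trans[IMAGINE] - trans[REST]) - (base[IMAGINE] - base[REST])
    return DRTResult(subject_id=subject_id, midbrain_drt=float(drt),
                     components={"imagine_transfer": trans[IMAGINE],
                                 "rest_transfer": trans[REST],
                                 "imagine_baseline": base[IMAGINE],
                                 "rest_baseline": base[REST]})


def compute_region_drt(baseline_fit: GLMFit, transfer_fit: GLMFit) -> float:
    """Non-midbrain DRT: transfer minus baseline IMAGINE - REST contrast."""
    return (imagine_minus_rest(transfer_fit)["estimate"]
            - imagine_minus_rest(baseline_fit)["estimate"])


def training_slope(fit_run1: GLMFit, fit_run2: GLMFit) -> float:
    """Second minus first training run's IMAGINE - REST contrast."""
    return (imagine_minus_rest(fit_run2)["estimate"]
            - imagine_minus_rest(fit_run1)["estimate"])


def td_slope(fit_run1: GLMFit, fit_run2: GLMFit,
             column: str = "imagine_td") -> float:
    """Second minus first training run's TD-modulator beta (dlPFC fits);
    becomes negative as temporal differences shrink with learning."""
    for fit in (fit_run1, fit_run2):
        if column not in fit.betas.index:
            raise MeasureError(f"fit lacks the {column!r} modulator beta")
    return fit_run2.beta(column) - fit_run1.beta(column)


def ppi_interaction(fit: GLMFit) -> dict:
    """IMAGINE - REST difference of the seed-interaction betas."""
    return run_contrast(fit, {"ppi_imagine": 1.0, "ppi_rest": -1.0},
                        name="ppi_imagine_minus_rest")


# ---------------------------------------------------------------------------
# MID gains


def mid_modulator_betas(fit: GLMFit) -> dict:
    """Reward-sensitivity summaries from a MID fit.

    sensitivity = beta_small + beta_large (general reward sensitivity);
    adaptive = beta_small - beta_large (adaptive reward coding).
    """
    bs, bl = fit.beta("mod_small"), fit.beta("mod_large")
    return {"beta_small": bs, "beta_large": bl,
            "sensitivity": bs + bl, "adaptive": bs - bl}


def recover_mid_gains(fit: GLMFit, small_range: float = 0.40,
                      large_range: float = 2.00) -> dict:
    """Invert the modulator betas to the generative gains.

    Per cue type the magnitude slope is general_gain + adaptive_gain / range,
    so the two betas identify both gains exactly.
    """
    bs, bl = fit.beta("mod_small"), fit.beta("mod_large")
    inv_s, inv_l = 1.0 / small_range, 1.0 / large_range
    adaptive = (bs - bl) / (inv_s - inv_l)
    general = bl - adaptive * inv_l
    return {"general_gain": float(general), "adaptive_gain": float(adaptive)}


# ---------------------------------------------------------------------------
# per-subject pipeline


def analyze_subject(dataset, *,
                    hemodynamic_shift: float = DEFAULT_HEMODYNAMIC_SHIFT,
                    prewhiten: bool = False) -> SubjectSummary:
    """Run preprocessing, GLMs and summary measures for one subject.

    Produces the SubjectSummary row feeding the group table: midbrain DRT,
    training slope (SN/VTA block contrasts), TD slope (dlPFC modulator
    betas), mean training-run PPI interaction (SN/VTA on dlPFC seed), and
    block-design region DRTs for dlPFC and the control region.
    """
    design = dataset.design
    nuisance = {r.run_type: nuisance_for_run(dataset, r.run_type)
                for r in design.runs}
    snvta = {r.run_type: dataset.roi_series[r.run_type]["SN_VTA"].to_numpy(float)
             for r in design.runs}
    dlpfc = {r.run_type: dataset.roi_series[r.run_type]["dlPFC"].to_numpy(float)
             for r in design.runs}
    control = {r.run_type:
               dataset.roi_series[r.run_type]["control_parahippocampus"]
               .to_numpy(float) for r in design.runs}

    drt = compute_drt(snvta["baseline"], design.run("baseline"),
                      snvta["transfer"], design.run("transfer"),
                      hemodynamic_shift, subject_id=design.subject_id)

    block_fits = {}
    for region_name, series in (("SN_VTA", snvta), ("dlPFC", dlpfc),
                                ("control", control)):
        for run in design.runs:
            dm = build_block_design(run, nuisance[run.run_type])
            block_fits[(region_name, run.run_type)] = fit_ols(
                dm, series[run.run_type], prewhiten=prewhiten)

    slope = training_slope(block_fits[("SN_VTA", "training1")],
                           block_fits[("SN_VTA", "training2")])
    dlpfc_drt = compute_region_drt(block_fits[("dlPFC", "baseline")],
                                   block_fits[("dlPFC", "transfer")])
    control_drt = compute_region_drt(block_fits[("control", "baseline")],
                                     block_fits[("control", "transfer")])

    td_fits = []
    ppi_vals = []
    for run in design.training_runs:
        rt = run.run_type
        td_fits.append(fit_ols(build_td_design(run, snvta[rt], nuisance[rt]),
                               dlpfc[rt], prewhiten=prewhiten))
        ppi_fit = fit_ols(build_ppi_design(dlpfc[rt], run, nuisance[rt]),
                          snvta[rt], prewhiten=prewhiten)
        ppi_vals.append(ppi_interaction(ppi_fit)["estimate"])
    tds = td_slope(td_fits[0], td_fits[1])

    return SubjectSummary(
        subject_id=design.subject_id, arm=design.arm, study_id=design.study_id,
        midbrain_drt=drt.midbrain_drt, training_slope=slope, td_slope=tds,
        ppi_estimate=float(np.mean(ppi_vals)), dlpfc_drt=dlpfc_drt,
        control_drt=control_drt)


def analyze_mid(mid_dataset, *, region: str = "dlPFC") -> dict:
    """Fit the MID design and return modulator summaries + recovered gains."""
    from .preprocess import pca_nuisance

    n = mid_dataset.n_volumes
    nuis = pca_nuisance(mid_dataset.csf_wm,
                        motion=mid_dataset.motion.to_numpy(float).T)
    dm = build_mid_design(mid_dataset.trials, n, mid_dataset.tr, nuis)
    fit = fit_ols(dm, mid_dataset.roi_series[region].to_numpy(float))
    out = mid_modulator_betas(fit)
    out.update(recover_mid_gains(fit))
    return out


def summaries_frame(summaries) -> pd.DataFrame:
    """SubjectSummary rows as a tidy table (one row per subject)."""
    df = pd.DataFrame([s.as_row() for s in summaries])
    if df["subject_id"].duplicated().any():
        raise MeasureError("duplicate subject ids in summary table")
    return df
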