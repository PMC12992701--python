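"""Panel readers/writers and the two preprocessing steps used in practice:
metabolite-wise age regression-out and reference-grid coarsening."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BiomarkerPanel

__all__ = [
    "read_panel",
    "write_panel",
    "regress_out_age",
    "map_to_reference_grid",
    "ReferenceGridMap",
]

logger = logging.getLogger(__name__)


def read_panel(path) -> BiomarkerPanel:
    """Read a long-format delimited file (subject, time, biomarker, value).

    Validates column presence, numeric times/values and uniqueness of
    (subject, time, biomarker) triples; logs panel dimensions and the
    visit-count histogram.
    """
    df = pd.read_csv(path)
    panel = BiomarkerPanel.from_long(df)
    counts = np.bincount(panel.q_i)
    logger.info(
        "panel: n=%d subjects, p=%d biomarkers, q=%d unique times; "
        "visit-count histogram=%s",
        panel.n, panel.p, panel.q,
        {v: int(c) for v, c in enumerate(counts) if c},
    )
    if np.any(panel.q_i < 2):
        logger.warning("%d subject(s) have fewer than 2 visits", int((panel.q_i < 2).sum()))
    return panel


def write_panel(panel: BiomarkerPanel, path) -> None:
    panel.to_long().to_csv(path, index=False)


def regress_out_age(panel: BiomarkerPanel, ages) -> BiomarkerPanel:
    """Residualize each biomarker on subject age by pooled OLS.

    ``ages`` maps subject id to age.  For each biomarker g an ordinary
    least-squares fit of x on intercept + age pools all (subject, time)
    observations; the returned panel holds the residuals, which have exactly
    zero sample correlation with age.
    """
    a = np.array([float(ages[s]) for s in panel.subjects])
    if np.ptp(a) == 0:
        raise ValueError("age is constant across subjects; regression is rank-deficient")
    a_obs = np.repeat(a, panel.q_i)
    design = np.column_stack([np.ones(a_obs.size), a_obs])
    Xcat = np.concatenate(panel.X, axis=1)              # p x N
    coef, *_ = np.linalg.lstsq(design, Xcat.T, rcond=None)
    resid = Xcat - (design @ coef).T
    starts = np.concatenate([[0], np.cumsum(panel.q_i)[:-1]])
    new_X = [resid[:, s:s + qi] for s, qi in zip(starts, panel.q_i)]
    return BiomarkerPanel(panel.subjects, panel.biomarkers, panel.grid,
                          panel.obs_idx, new_X)


@dataclass(frozen=True)
class ReferenceGridMap:
    """Record of an original-to-reference time mapping.

    ``mapping`` lists (subject, original_time, reference_time) triples for
    every retained observation; ``dropped`` lists visits discarded because two
    original visits of one subject collapsed onto the same reference time.
    ``shift_sd`` gives, per subject, the standard deviation of the signed
    shifts (original - reference): small values mean the mapping amounts to an
    approximately constant per-subject time shift, which is harmless under a
    stationary covariance.
    """

    ref_times: np.ndarray
    mapping: pd.DataFrame
    dropped: pd.DataFrame
    shift_sd: dict

    @property
    def max_shift_sd(self) -> float:
        return max(self.shift_sd.values()) if self.shift_sd else 0.0


def map_to_reference_grid(panel: BiomarkerPanel, ref_times) -> tuple[BiomarkerPanel, ReferenceGridMap]:
    """Coarsen observation times onto a reference grid.

    Each observed time maps to the nearest reference time (ties resolved to
    the earlier one).  When two visits of one subject land on the same
    reference time, the earlier visit is kept and the later dropped (logged).
    """
    ref = np.asarray(ref_times, dtype=float)
    if ref.size == 0:
        raise ValueError("reference grid is empty")
    if np.any(np.diff(ref) <= 0):
        raise ValueError("reference times must be sorted and unique")

    def nearest(t: float) -> int:
        d = np.abs(ref - t)
        return int(np.flatnonzero(d == d.min())[0])   # first minimum = earlier tie

    map_rows, drop_rows, shift_sd = [], [], {}
    new_obs_idx, new_X = [], []
    used_ref = set()
    per_subject = []
    for i, s in enumerate(panel.subjects):
        times = panel.times(i)
        assigned: dict[int, int] = {}
        shifts = []
        for j, t in enumerate(times):
            r = nearest(float(t))
            if r in assigned:
                drop_rows.append((s, float(t), float(ref[r])))
                continue
            assigned[r] = j
            shifts.append(float(t) - float(ref[r]))
            map_rows.append((s, float(t), float(ref[r])))
        shift_sd[s] = float(np.std(shifts)) if len(shifts) > 1 else 0.0
        rs = sorted(assigned)
        used_ref.update(rs)
        per_subject.append((rs, panel.X[i][:, [assigned[r] for r in rs]]))

    used = sorted(used_ref)
    remap = {r: j for j, r in enumerate(used)}
    for rs, x in per_subject:
        new_obs_idx.append(np.array([remap[r] for r in rs]))
        new_X.append(x)
    for s, t, r in drop_rows:
        logger.warning("subject %s: visit at t=%g dropped (collides at reference %g)", s, t, r)
    coarse = BiomarkerPanel(panel.subjects, panel.biomarkers, ref[used],
                            new_obs_idx, new_X)
    gm = ReferenceGridMap(
        ref_times=ref,
        mapping=pd.DataFrame(map_rows, columns=["subject", "time", "ref_time"]),
        dropped=pd.DataFrame(drop_rows, columns=["subject", "time", "ref_time"]),
        shift_sd=shift_sd,
    )
    return coarse, gm
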