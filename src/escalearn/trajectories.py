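"""Assemble per-trial HGF quantities into analysis-ready long tables.

For every usable subject x condition fit, the filter is re-run at the
MAP estimates on that condition's input sequence and eight outcome
series (mu2, mu3, sigma2, sigma3, eps2, eps3, psi2, psi3) are stacked
into one long table keyed by subject, group, condition and the
*overall* task trial number (1..120, raw, uncentered).  Coding follows
the reference levels used throughout: group 0 = no SI history,
condition 0 = avoidance.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .hgf import TRAJECTORY_OUTCOMES, filter_sequence
from .inversion import FitResult, PriorSpec

__all__ = ["LONG_COLUMNS", "extract_trajectories", "write_long", "read_long", "plot_trajectories"]

log = logging.getLogger(__name__)

LONG_COLUMNS = ["subject_id", "group", "condition", "trial", "outcome", "value"]

_GROUP_CODE = {"NoSI": 0, "SI": 1}
_COND_CODE = {"avoidance": 0, "escape": 1}


class SchemaError(ValueError):
    """Long-table file does not match the expected schema."""


def extract_trajectories(
    fits: list[FitResult],
    dataset: pd.DataFrame,
    priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """Re-run the filter at each MAP estimate and emit the long table.

    Subjects with a failed fit for either condition are excluded (and
    logged); all remaining cells are complete by construction — there
    is no missing trial-level data.
    """
    priors = priors or PriorSpec()
    fit_map = {(f.subject_id, f.condition): f for f in fits}
    bad_subjects = {f.subject_id for f in fits if not f.usable}
    if bad_subjects:
        log.warning("excluding %d subjects with failed fits: %s", len(bad_subjects), sorted(bad_subjects))

    blocks = []
    for (sid, cond), sd in dataset.groupby(["subject_id", "condition"], sort=True):
        if sid in bad_subjects:
            continue
        fit = fit_map.get((sid, cond)) or fit_map.get((sid, "all"))
        if fit is None:
            log.warning("no fit for subject %s condition %s; excluded", sid, cond)
            continue
        sd = sd.sort_values("trial")
        params = priors.to_params(np.array([fit.omega2, fit.omega3, np.log(fit.beta)]))
        traj = filter_sequence(sd["u"].to_numpy(dtype=int), params)
        base = {
            "subject_id": sid,
            "group": _GROUP_CODE[sd["group"].iloc[0]],
            "condition": _COND_CODE[cond],
        }
        trials = sd["trial"].to_numpy()
        for outcome in TRAJECTORY_OUTCOMES:
            vals = traj.series(outcome)
            blocks.append(
                pd.DataFrame(
                    {
                        **base,
                        "trial": trials,
                        "outcome": outcome,
                        "value": vals,
                    }
                )
            )
    if not blocks:
        return pd.DataFrame(columns=LONG_COLUMNS)
    out = pd.concat(blocks, ignore_index=True)[LONG_COLUMNS]
    return out.sort_values(["subject_id", "outcome", "trial"], kind="stable").reset_index(drop=True)


def write_long(table: pd.DataFrame, path: str | Path, *, header_lines: list[str] | None = None) -> None:
    """Write the long table as CSV at full precision (LF line endings)."""
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"long table missing columns: {missing}")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def read_long(path: str | Path) -> pd.DataFrame:
    """Read a long table, validating the header schema."""
    try:
        table = pd.read_csv(path, comment="#", encoding="utf-8")
    except UnicodeDecodeError as err:
        raise SchemaError(f"{path} is not valid UTF-8: {err}") from None
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path} missing columns: {missing}")
    return table[LONG_COLUMNS]


def plot_trajectories(long_table: pd.DataFrame, outcome: str, ax=None):
    """Mean +/- s.e. band of one outcome over trials, by group.

    Optional convenience figure (matplotlib); returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = long_table[long_table["outcome"] == outcome]
    for g, label, color in ((0, "No SI history", "tab:blue"), (1, "SI history", "tab:red")):
        gd = sub[sub["group"] == g].groupby("trial")["value"]
        m, se = gd.mean(), gd.sem()
        ax.plot(m.index, m.values, label=label, color=color)
        ax.fill_between(m.index, m - se, m + se, alpha=0.25, color=color, lw=0)
    ax.set_xlabel("trial")
    ax.set_ylabel(outcome)
    ax.legend(frameon=False)
    return ax
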