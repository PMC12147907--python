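"""Group-level statistics for paired-eye designs, marker-profile
clustering, and the Monte-Carlo parameter-recovery harness.

The paired t-test and the two-way repeated-measures ANOVA are computed
from their textbook sums-of-squares formulas (p-values via the standard
t and F distributions); the marker clustering uses correlation distance
(1 - Pearson's r) with unweighted average linkage.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import InputError
from .pipeline import AnalysisConfig, decompose_recording
from .simulate import CohortDesign, simulate_cohort

#: ground-truth parameters the decomposition estimates, mapped to the
#: metrics column holding the estimate
RECOVERABLE_PARAMS = {
    "rmp3_uv": "rmp3_uv",
    "s_sens": "s_sens",
    "td_ms": "td_ms",
    "p2max_uv": "p2max_uv",
    "k_semisat": "k_semisat",
    "pstr_amp_uv": "pstr_m530_uv",
}


def paired_t(x, y):
    """Paired t-test of two matched samples.

    Computes t = mean(d) / (sd(d) / sqrt(n)) with d = x - y and
    df = n - 1; the two-sided p-value comes from the t distribution.

    Returns
    -------
    (t, df, p)

    Raises
    ------
    InputError
        For n < 2, or when the differences have zero variance around a
        non-zero mean (p undefined).  Identical samples (all d = 0)
        return t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired_t needs two 1-D samples of equal length")
    n = len(x)
    if n < 2:
        raise InputError(f"paired_t needs >= 2 pairs, got {n}")
    d = x - y
    if np.all(d == 0):
        return 0.0, n - 1, 1.0
    sd = d.std(ddof=1)
    if sd == 0:
        raise InputError(
            "differences have zero variance around a non-zero mean; "
            "p is undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def paired_table(metrics: pd.DataFrame, column: str) -> pd.DataFrame:
    """Pivot per-eye metrics into one row per subject (NT vs. OHT).

    Subjects missing either eye are dropped; the treatment label is
    carried along.
    """
    wide = metrics.pivot_table(
        index=["subject_id", "treatment_group"],
        columns="pressure_group", values=column, aggfunc="first",
    ).reset_index()
    wide = wide.dropna(subset=["NT", "OHT"])
    return wide.rename_axis(columns=None)


def rm_anova2(data: pd.DataFrame, subject="subject", group="group",
              time="time", value="value") -> pd.DataFrame:
    """Two-way repeated-measures ANOVA: between-subject group, within-
    subject time (split-plot design).

    The classical sums-of-squares decomposition is computed explicitly:
    the group effect is tested against subjects-within-groups, the time
    and group x time effects against the time x subject-within-group
    residual.  Only balanced complete designs are supported (every
    subject observed at every time, one group per subject); no
    sphericity correction is applied.

    Returns
    -------
    DataFrame indexed by effect (group, time, interaction) with columns
    ss, df1, df2, F, p.  When every value is identical all sums of
    squares are zero and F = 0, p = 1 by convention.
    """
    df = data[[subject, group, time, value]].copy()
    df.columns = ["subject", "group", "time", "value"]

    g_per_subj = df.groupby("subject")["group"].nunique()
    if (g_per_subj != 1).any():
        raise InputError("each subject must belong to exactly one group")
    counts = df.groupby(["subject", "time"]).size()
    if (counts != 1).any():
        raise InputError(
            "unbalanced design: every subject needs exactly one value per time"
        )
    times = df["time"].unique()
    t_count = len(times)
    per_subj = df.groupby("subject")["time"].nunique()
    if (per_subj != t_count).any():
        raise InputError("unbalanced design: missing subject x time cells")
    subj_group = df.groupby("subject")["group"].first()
    if subj_group.groupby(subj_group).size().nunique() > 1:
        raise InputError("unbalanced design: groups differ in subject count")

    y = df["value"].to_numpy(dtype=float)
    gm = y.mean()
    n_subj = df["subject"].nunique()
    a = df["group"].nunique()

    ss_total = float(((y - gm) ** 2).sum())

    subj_means = df.groupby("subject")["value"].mean()
    ss_between_subj = float(t_count * ((subj_means - gm) ** 2).sum())

    grp_means = df.groupby("group")["value"].mean()
    grp_nsubj = subj_group.groupby(subj_group).size()
    ss_group = float(sum(
        grp_nsubj[g] * t_count * (grp_means[g] - gm) ** 2 for g in grp_means.index
    ))
    ss_subj_within = ss_between_subj - ss_group

    time_means = df.groupby("time")["value"].mean()
    ss_time = float(n_subj * ((time_means - gm) ** 2).sum())

    cell = df.groupby(["group", "time"])["value"].agg(["mean", "size"])
    ss_cells = float((cell["size"] * (cell["mean"] - gm) ** 2).sum())
    ss_interaction = ss_cells - ss_group - ss_time

    ss_within_total = ss_total - ss_between_subj
    ss_error = ss_within_total - ss_time - ss_interaction

    rows = {}
    specs = [
        ("group", ss_group, a - 1, ss_subj_within, n_subj - a),
        ("time", ss_time, t_count - 1, ss_error, (n_subj - a) * (t_count - 1)),
        ("interaction", ss_interaction, (a - 1) * (t_count - 1),
         ss_error, (n_subj - a) * (t_count - 1)),
    ]
    for name, ss, df1, ss_err, df2 in specs:
        if df1 < 1 or df2 < 1:
            raise InputError(f"not enough levels/subjects to test {name}")
        ms_err = ss_err / df2
        if ms_err == 0:
            f_stat, p = (0.0, 1.0)  # degenerate: no residual variation
        else:
            f_stat = (ss / df1) / ms_err
            p = float(sps.f.sf(f_stat, df1, df2))
        rows[name] = {"ss": ss, "df1": df1, "df2": df2, "F": float(f_stat), "p": p}
    out = pd.DataFrame(rows).T
    out.attrs["ss_subjects_within_groups"] = ss_subj_within
    out.attrs["ss_error_within"] = ss_error
    out.attrs["ss_total"] = ss_total
    return out


def corr_average_linkage(matrix, k: int | None = None):
    """Hierarchical clustering with correlation distance, average linkage.

    Parameters
    ----------
    matrix
        2-D array or DataFrame, one row per profile (e.g. one optic
        nerve), one column per marker variable.
    k
        If given, also cut the tree into ``k`` flat clusters.

    Returns
    -------
    (Z, clusters) where ``Z`` is the standard (n-1) x 4 merge table
    (cluster a, cluster b, height, size) and ``clusters`` the 1-based
    flat labels (or None).  Distance is d(a, b) = 1 - Pearson(a, b), so
    rows equal up to a positive affine transform are at distance 0.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise InputError("matrix entries must be finite")
    variances = X.var(axis=1)
    for idx in np.nonzero(variances == 0)[0]:
        raise InputError(
            f"row {idx} is constant; correlation distance is undefined for it"
        )
    d = pdist(X, metric="correlation")
    Z = linkage(d, method="average")
    clusters = fcluster(Z, t=k, criterion="maxclust") if k is not None else None
    return Z, clusters


def pstr_power_simulation(
    n_pairs: int,
    effect: float,
    n_cohorts: int,
    seed: int,
    base=None,
    inter_animal_cv: float = 0.2,
    alpha: float = 0.05,
    intensity_log: float = -5.30,
) -> float:
    """Rejection rate of the paired pSTR test over simulated cohorts.

    Simulates ``n_cohorts`` paired-eye cohorts in which the OHT eye's
    pSTR amplitude is ``effect`` times its NT partner's, measures the
    pSTR stage of the pipeline on each eye (baseline correction, 50 Hz
    low-pass, positive-lobe peak) and runs the paired t-test at level
    ``alpha``.  Returns the fraction of cohorts rejecting with the OHT
    mean below the NT mean.
    """
    from .filters import p2_lowpass
    from .p2 import pstr_amplitude
    from .simulate import ComponentParams

    if base is None:
        base = ComponentParams()
    lowpass = None
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    rejections = 0
    for s in seeds:
        design = CohortDesign(
            n_pairs=n_pairs, base=base, inter_animal_cv=inter_animal_cv,
            seed=int(s) & 0x7FFFFFFF, effects={"pstr_amp_uv": effect},
        )
        recordings, _ = simulate_cohort(design)
        if lowpass is None:
            lowpass = p2_lowpass(recordings[0].fs_hz)
        nt, oht = [], []
        for rec in recordings:
            trace = rec.trace_at(intensity_log)
            trace = trace.with_voltage(trace.v_uv - trace.baseline())
            amp = pstr_amplitude(lowpass.apply(trace),
                                 intensity_log=intensity_log)
            (nt if rec.pressure_group == "NT" else oht).append(amp)
        t, _, p = paired_t(np.asarray(oht), np.asarray(nt))
        if p < alpha and t < 0:
            rejections += 1
    return rejections / n_cohorts


def recovery_harness(
    design: CohortDesign,
    n_replicates: int,
    seed: int,
    config: AnalysisConfig | None = None,
    params=None,
) -> pd.DataFrame:
    """Monte-Carlo parameter recovery over repeated simulated cohorts.

    Each replicate simulates a fresh cohort from a seed derived from
    ``seed``, runs the full decomposition on every eye and records the
    per-eye relative estimation error of each recoverable parameter.
    Replicates whose decomposition raises are counted as failures, not
    fatal.

    Returns
    -------
    DataFrame with one row per parameter: true_mean, est_mean, rel_bias,
    rel_rmse, n_eyes, n_replicates, n_failures, seed.  rel_rmse >=
    |rel_bias| always.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    if params is None:
        params = dict(RECOVERABLE_PARAMS)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    errors = {name: [] for name in params}
    truths = {name: [] for name in params}
    estimates = {name: [] for name in params}
    n_failures = 0
    for rep in range(n_replicates):
        rep_design = replace(design, seed=int(child_seeds[rep]) & 0x7FFFFFFF)
        recordings, truth = simulate_cohort(rep_design)
        truth = truth.set_index(["subject_id", "eye"])
        for rec in recordings:
            try:
                metrics = decompose_recording(rec, config)
            except Exception:
                n_failures += 1
                continue
            true_row = truth.loc[(rec.subject_id, rec.eye)]
            for name, est_col in params.items():
                true_val = float(true_row[name])
                est_val = float(metrics[est_col])
                truths[name].append(true_val)
                estimates[name].append(est_val)
                errors[name].append((est_val - true_val) / true_val)

    rows = []
    for name in params:
        err = np.asarray(errors[name])
        rows.append({
            "parameter": name,
            "true_mean": float(np.mean(truths[name])) if len(err) else np.nan,
            "est_mean": float(np.mean(estimates[name])) if len(err) else np.nan,
            "rel_bias": float(err.mean()) if len(err) else np.nan,
            "rel_rmse": float(np.sqrt((err**2).mean())) if len(err) else np.nan,
            "median_abs_rel_err": float(np.median(np.abs(err))) if len(err) else np.nan,
            "n_eyes": int(len(err)),
            "n_replicates": n_replicates,
            "n_failures": n_failures,
            "seed": seed,
        })
    return pd.DataFrame(rows).set_index("parameter")
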