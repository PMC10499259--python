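"""Per-feature permutation statistics for the within-subject design.

The screening test is a randomized (permutation) repeated-measures ANOVA:
the observed F comes from the one-way RM-ANOVA with subject as blocking
factor, and the null distribution from independently permuting the condition
labels within each subject — exact under the within-subject null, and cheap
to enumerate on tiny designs.  P-values use the add-one correction
p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).

Post hoc pairwise comparisons are paired t statistics with sign-flip
permutation of the subject-matched differences, Benjamini-Hochberg adjusted
across the condition pairs of one feature (not across features; the study
design applies no correction across the 229 parameters).

A two-way mixed-design variant (emotion within, gender between) permutes
condition labels within subjects for the emotion and interaction effects and
gender labels across subjects for the gender effect.

Subjects with missing cells are dropped listwise per feature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mocap_io import CONDITIONS

META = ("subject_id", "gender", "condition")


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def complete_case_matrix(
    table: pd.DataFrame, feature: str, conditions: tuple[str, ...] = CONDITIONS
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Subjects x conditions value matrix, complete cases only.

    Returns (Y, subject_ids, gender) with one row per subject having a
    non-missing value in every condition.
    """
    if feature not in table.columns:
        raise KeyError(feature)
    wide = table.pivot(index="subject_id", columns="condition", values=feature)
    cols = [c for c in conditions if c in wide.columns]
    wide = wide[cols].dropna()
    gender = (
        table.drop_duplicates("subject_id").set_index("subject_id")["gender"]
        .reindex(wide.index)
        .to_numpy()
    )
    return wide.to_numpy(float), list(wide.index), gender


# ---------------------------------------------------------------------------
# One-way repeated-measures ANOVA + permutation
# ---------------------------------------------------------------------------

def rm_anova_f(Y: np.ndarray) -> float:
    """One-way repeated-measures F (subject as blocking factor)."""
    n, k = Y.shape
    gm = Y.mean()
    ss_tot = ((Y - gm) ** 2).sum()
    ss_sub = k * ((Y.mean(axis=1) - gm) ** 2).sum()
    ss_cond = n * ((Y.mean(axis=0) - gm) ** 2).sum()
    ss_err = ss_tot - ss_sub - ss_cond
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_err <= 1e-300:
        return np.inf if ss_cond > 1e-300 else 0.0
    return float((ss_cond / df1) / (ss_err / df2))


def _f_from_colsums(colsums: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """F statistics for permuted column sums (within-row permutations leave
    row means and the total SS invariant)."""
    n, k = Y.shape
    gm = Y.mean()
    ss_tot = ((Y - gm) ** 2).sum()
    ss_sub = k * ((Y.mean(axis=1) - gm) ** 2).sum()
    ss_cond = (colsums**2).sum(axis=-1) / n - n * k * gm * gm
    ss_err = ss_tot - ss_sub - ss_cond
    df1, df2 = k - 1, (n - 1) * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    f = np.where(ss_err <= 1e-12 * max(ss_tot, 1e-300), np.inf, f)
    return f


def _permuted_colsums(
    Y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n, k = Y.shape
    idx = rng.random((n_perm, n, k)).argsort(axis=-1)
    Yp = np.take_along_axis(np.broadcast_to(Y, (n_perm, n, k)), idx, axis=-1)
    return Yp.sum(axis=1)


def _exhaustive_colsums(Y: np.ndarray) -> np.ndarray:
    n, k = Y.shape
    perms = list(itertools.permutations(range(k)))
    rows = [np.array([Y[i, list(p)] for p in perms]) for i in range(n)]
    sums = np.zeros((1, k))
    for row_variants in rows:
        sums = (sums[:, None, :] + row_variants[None, :, :]).reshape(-1, k)
    return sums


def n_exhaustive(n_subjects: int, k: int) -> int:
    import math

    return math.factorial(k) ** n_subjects


@dataclass
class PermAnovaResult:
    feature: str
    f_observed: float
    p_perm: float
    n_permutations: int
    n_subjects: int
    pairwise: list[dict] = field(default_factory=list)


def perm_rm_anova(
    table: pd.DataFrame,
    feature: str,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> PermAnovaResult:
    """Randomized repeated-measures ANOVA for one feature.

    ``exhaustive=True`` (or auto, when the within-subject permutation space is
    not larger than ``n_perm``) enumerates every within-subject label
    permutation instead of sampling.
    """
    Y, subjects, _ = complete_case_matrix(table, feature)
    n, k = Y.shape
    if k < 2:
        raise ValueError("need at least two conditions with data")
    if n < 2:
        raise ValueError("need at least two complete subjects")
    f_obs = rm_anova_f(Y)
    if exhaustive is None:
        exhaustive = n_exhaustive(n, k) <= n_perm
    if exhaustive:
        colsums = _exhaustive_colsums(Y)
        f_perm = _f_from_colsums(colsums, Y)
        # exhaustive: exact p, the identity permutation is included
        p = float((f_perm >= f_obs - 1e-12).sum() / f_perm.shape[0])
        n_used = f_perm.shape[0]
    else:
        rng = np.random.default_rng(seed)
        colsums = _permuted_colsums(Y, n_perm, rng)
        f_perm = _f_from_colsums(colsums, Y)
        p = float(((f_perm >= f_obs - 1e-12).sum() + 1) / (n_perm + 1))
        n_used = n_perm
    return PermAnovaResult(feature, f_obs, p, n_used, n)


# ---------------------------------------------------------------------------
# Pairwise sign-flip t tests with BH-FDR
# ---------------------------------------------------------------------------

def _paired_t(d: np.ndarray) -> float:
    n = d.shape[0]
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    return float(d.mean() / (sd / np.sqrt(n)))


def _signflip_p(d: np.ndarray, n_perm: int, rng, exhaustive: bool) -> tuple[float, float, int]:
    n = d.shape[0]
    t_obs = _paired_t(d)
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    ds = signs * d
    m = ds.mean(axis=1)
    sd = ds.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m / (sd / np.sqrt(n))
    t_perm = np.nan_to_num(t_perm, nan=0.0)
    if exhaustive:
        p = float((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum() / signs.shape[0])
        n_used = signs.shape[0]
    else:
        p = float(((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum() + 1) / (n_perm + 1))
        n_used = n_perm
    return t_obs, p, n_used


def perm_pairwise(
    table: pd.DataFrame,
    feature: str,
    pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 1_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[dict]:
    """Randomized paired t-tests for condition pairs, BH-FDR adjusted across
    the pairs of this feature."""
    wide = table.pivot(index="subject_id", columns="condition", values=feature)
    if pairs is None:
        present = [c for c in CONDITIONS if c in wide.columns]
        pairs = list(itertools.combinations(present, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        d = (wide[a] - wide[b]).dropna().to_numpy(float)
        if d.shape[0] < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
        t_obs, p, n_used = _signflip_p(d, n_perm, rng, exhaustive)
        rows.append(
            {"pair": (a, b), "t_observed": t_obs, "p_perm": p,
             "n_permutations": n_used, "n_pairs": d.shape[0]}
        )
    p_adj = multipletests([r["p_perm"] for r in rows], method="fdr_bh")[1]
    for r, q in zip(rows, p_adj):
        r["p_fdr"] = float(q)
    return rows


# ---------------------------------------------------------------------------
# Two-way mixed design (emotion within, gender between)
# ---------------------------------------------------------------------------

def _mixed_f(Y: np.ndarray, groups: np.ndarray) -> dict[str, float]:
    """F statistics of the mixed-design ANOVA (between: gender, within:
    condition)."""
    n, k = Y.shape
    labels = np.unique(groups)
    G = labels.shape[0]
    gm = Y.mean()
    rows = Y.mean(axis=1)
    ss_tot = ((Y - gm) ** 2).sum()
    ss_between_subj = k * ((rows - gm) ** 2).sum()
    ss_within = ss_tot - ss_between_subj
    ss_gender = k * sum(
        (groups == g).sum() * (rows[groups == g].mean() - gm) ** 2 for g in labels
    )
    ss_subj_within = ss_between_subj - ss_gender
    cols = Y.mean(axis=0)
    ss_cond = n * ((cols - gm) ** 2).sum()
    ss_int = 0.0
    for g in labels:
        sel = groups == g
        cell = Y[sel].mean(axis=0)
        ss_int += sel.sum() * ((cell - rows[sel].mean() - cols + gm) ** 2).sum()
    ss_err = ss_within - ss_cond - ss_int

    def ratio(ss1, df1, ss2, df2):
        if ss2 <= 1e-300:
            return np.inf if ss1 > 1e-300 else 0.0
        return float((ss1 / df1) / (ss2 / df2))

    return {
        "gender": ratio(ss_gender, G - 1, ss_subj_within, n - G),
        "emotion": ratio(ss_cond, k - 1, ss_err, (n - G) * (k - 1)),
        "interaction": ratio(ss_int, (G - 1) * (k - 1), ss_err, (n - G) * (k - 1)),
    }


def perm_two_way(
    table: pd.DataFrame,
    feature: str,
    n_perm: int = 2_000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Permutation mixed-design ANOVA: emotion (within), gender (between),
    and their interaction."""
    Y, subjects, gender = complete_case_matrix(table, feature)
    n, k = Y.shape
    if np.unique(gender).shape[0] < 2:
        raise ValueError("both genders must be represented")
    obs = _mixed_f(Y, gender)
    rng = np.random.default_rng(seed)

    # within-subject permutations: emotion and interaction effects
    count_emotion = 0
    count_inter = 0
    for _ in range(n_perm):
        idx = rng.random((n, k)).argsort(axis=-1)
        Yp = np.take_along_axis(Y, idx, axis=-1)
        f = _mixed_f(Yp, gender)
        count_emotion += f["emotion"] >= obs["emotion"] - 1e-12
        count_inter += f["interaction"] >= obs["interaction"] - 1e-12
    # gender-label permutations across subjects
    count_gender = 0
    for _ in range(n_perm):
        f = _mixed_f(Y, rng.permutation(gender))
        count_gender += f["gender"] >= obs["gender"] - 1e-12

    return {
        "emotion": {"F": obs["emotion"], "p_perm": (count_emotion + 1) / (n_perm + 1)},
        "gender": {"F": obs["gender"], "p_perm": (count_gender + 1) / (n_perm + 1)},
        "interaction": {"F": obs["interaction"], "p_perm": (count_inter + 1) / (n_perm + 1)},
        "n": {"subjects": n, "permutations": n_perm},
    }


# ---------------------------------------------------------------------------
# Screening all features
# ---------------------------------------------------------------------------

def screen_all(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    pairwise: bool = False,
    n_perm_pairwise: int = 1_000,
    two_way: bool = False,
    n_perm_two_way: int = 2_000,
) -> pd.DataFrame:
    """Per-feature permutation RM-ANOVA over every feature column.

    Returns a frame with observed F, permutation p, subject count and
    significance flags; optionally BH-adjusted pairwise results (for features
    passing the screen) and two-way interaction p-values.
    """
    features = [c for c in table.columns if c not in META]
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(3 * len(features))
    for i, feat in enumerate(features):
        rec: dict = {"feature": feat}
        try:
            res = perm_rm_anova(table, feat, n_perm=n_perm, seed=int(seeds[3 * i] % 2**31))
            rec.update(
                F=res.f_observed, p_perm=res.p_perm, n_subjects=res.n_subjects,
                significant=res.p_perm < alpha,
            )
        except (ValueError, KeyError) as exc:
            rec.update(F=np.nan, p_perm=np.nan, n_subjects=0, significant=False,
                       error=str(exc))
            rows.append(rec)
            continue
        if pairwise and rec["significant"]:
            try:
                pw = perm_pairwise(
                    table, feat, n_perm=n_perm_pairwise,
                    seed=int(seeds[3 * i + 1] % 2**31),
                )
                rec["n_pairs_significant"] = sum(r["p_fdr"] < alpha for r in pw)
            except ValueError:
                rec["n_pairs_significant"] = np.nan
        if two_way:
            try:
                tw = perm_two_way(
                    table, feat, n_perm=n_perm_two_way,
                    seed=int(seeds[3 * i + 2] % 2**31),
                )
                rec["p_interaction"] = tw["interaction"]["p_perm"]
                rec["interaction_significant"] = rec["p_interaction"] < alpha
            except ValueError:
                rec["p_interaction"] = np.nan
                rec["interaction_significant"] = False
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("feature")
    df.attrs["n_significant"] = int(df["significant"].sum())
    df.attrs["alpha"] = alpha
    if two_way and "interaction_significant" in df:
        df.attrs["n_interaction_significant"] = int(df["interaction_significant"].sum())
    return df


# ---------------------------------------------------------------------------
# Sensitivity / power simulation
# ---------------------------------------------------------------------------

def sensitivity_power(
    f: float,
    n_subjects: int = 24,
    n_conditions: int = 5,
    corr: float = 0.5,
    alpha: float = 0.05,
    n_reps: int = 1_000,
    n_perm: int = 2_000,
    seed: int = 0,
) -> float:
    """Simulated power of the permutation RM-ANOVA.

    Data follow a normal repeated-measures model with total within-condition
    variance 1 split into a subject component (variance ``corr``) and a
    residual (variance 1-corr); condition means have standard deviation
    ``f`` (Cohen's f).  Returns the fraction of replicates with p < alpha.
    """
    if not 0 <= corr < 1:
        raise ValueError("corr must be in [0, 1)")
    k = n_conditions
    base = np.linspace(-1.0, 1.0, k)
    base = base - base.mean()
    scale = f / np.sqrt((base**2).mean()) if f > 0 else 0.0
    mu = base * scale
    root = np.random.SeedSequence(seed)
    hits = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        subj = rng.normal(0.0, np.sqrt(corr), size=(n_subjects, 1))
        eps = rng.normal(0.0, np.sqrt(1.0 - corr), size=(n_subjects, k))
        Y = mu[None, :] + subj + eps
        f_obs = rm_anova_f(Y)
        colsums = _permuted_colsums(Y, n_perm, rng)
        f_perm = _f_from_colsums(colsums, Y)
        p = ((f_perm >= f_obs - 1e-12).sum() + 1) / (n_perm + 1)
        hits += p < alpha
    return hits / n_reps
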