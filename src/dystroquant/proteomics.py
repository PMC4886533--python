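"""Label-free LC-MS differential-abundance analysis.

Starting from a peptide-feature table (downstream of peak picking and
database searching), this module applies the quantification and statistics
stage of the study design it targets: retain features with charge 2+..7+,
normalise runs by median log-ratio to a reference run, roll peptides up to
proteins as the sum of unique-peptide abundances, QC replicate agreement by
pairwise R² of log abundances, and test Dys-vs-WT differential abundance
per age group by one-way ANOVA with Bonferroni correction.

Significance tiers follow the study convention: p < 0.05 is *moderate*
evidence and Bonferroni q < 0.05 (q = p x number of proteins tested,
capped at 1) is *strong* evidence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PEPTIDE_COLUMNS = ("peptide", "charge", "accessions", "run_id", "abundance")
CHARGE_RANGE = (2, 7)
P_THRESHOLD = 0.05
Q_THRESHOLD = 0.05


class SchemaError(ValueError):
    """Input table lacks a required column."""


class NormalizationError(ValueError):
    """Too little feature overlap with the reference run to normalise."""


@dataclass(frozen=True)
class ProteinAbundanceMatrix:
    """Protein x run abundances from unique-peptide rollup.

    ``matrix`` is a proteins-by-runs DataFrame (missing values are 0: in
    label-free data absence is informative).  Provenance counts record the
    peptides used and excluded.
    """

    matrix: pd.DataFrame
    n_unique_peptides: int
    n_shared_excluded: int


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = set(cols) - set(table.columns)
    if missing:
        raise SchemaError(f"peptide table lacks columns: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """Retain features with charge 2+ to 7+ (inclusive)."""
    _require_columns(table, ("charge",))
    lo, hi = CHARGE_RANGE
    keep = table["charge"].between(lo, hi)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_peptides: dropped %d feature rows outside %d+..%d+",
                    dropped, lo, hi)
    return table.loc[keep].reset_index(drop=True)


def normalize_runs(
    table: pd.DataFrame,
    design: pd.DataFrame | None = None,
    min_shared: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-log-ratio normalization of run abundances.

    The run with the most observed features is the reference; every other
    run is scaled so the median log-ratio of its shared features to the
    reference is zero.  Returns the scaled table and the per-run scale
    factors applied.  Idempotent up to machine tolerance.
    """
    _require_columns(table, ("peptide", "run_id", "abundance"))
    wide = table.pivot_table(index="peptide", columns="run_id",
                             values="abundance", aggfunc="sum")
    counts = wide.notna().sum(axis=0)
    reference = counts.sort_index().idxmax()  # ties -> lexicographically first

    factors = {}
    ref = wide[reference]
    for run in wide.columns:
        both = wide[run].notna() & ref.notna() & (wide[run] > 0) & (ref > 0)
        if int(both.sum()) < min_shared:
            raise NormalizationError(
                f"run {run!r} shares only {int(both.sum())} usable features "
                f"with reference {reference!r}")
        med = np.median(np.log(wide.loc[both, run] / ref[both]))
        factors[run] = float(np.exp(-med))

    factors = pd.Series(factors, name="scale_factor").sort_index()
    out = table.copy()
    out["abundance"] = out["abundance"] * out["run_id"].map(factors).to_numpy()
    logger.info("normalize_runs: reference=%s factors=%s", reference,
                factors.round(4).to_dict())
    return out, factors


# ---------------------------------------------------------------------------
# Protein rollup
# ---------------------------------------------------------------------------

def rollup_proteins(table: pd.DataFrame) -> ProteinAbundanceMatrix:
    """Sum unique-peptide abundances per protein and run.

    Peptides mapping to more than one accession are excluded from
    quantification entirely; a missing peptide contributes 0 to the sum.
    """
    _require_columns(table, PEPTIDE_COLUMNS)
    if len(table) == 0:
        raise ValueError("empty peptide table")
    acc = table["accessions"].astype(str)
    unique = ~acc.str.contains(";", regex=False)
    n_shared = int((~unique).sum())
    kept = table.loc[unique]
    if len(kept) == 0:
        raise ValueError("no unique peptides: cannot quantify any protein")
    matrix = kept.pivot_table(index="accessions", columns="run_id",
                              values="abundance", aggfunc="sum",
                              fill_value=0.0)
    matrix = matrix.reindex(columns=sorted(table["run_id"].unique()),
                            fill_value=0.0)
    matrix.index.name = "protein"
    return ProteinAbundanceMatrix(
        matrix=matrix,
        n_unique_peptides=int(kept["peptide"].nunique()),
        n_shared_excluded=n_shared,
    )


# ---------------------------------------------------------------------------
# Replicate-correlation QC
# ---------------------------------------------------------------------------

def replicate_correlation(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    min_shared: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise R² of log10 abundances between runs, plus group means.

    Zeros are excluded pairwise (log of a zero abundance is undefined);
    pairs sharing fewer than ``min_shared`` nonzero proteins are flagged
    and left out of the averages.  The summary reports the mean R² within
    (genotype, age) groups and between genotypes at matched age.
    """
    meta = design.set_index("run_id")
    rows = []
    for a, b in itertools.combinations(sorted(matrix.columns), 2):
        x, y = matrix[a].to_numpy(float), matrix[b].to_numpy(float)
        ok = (x > 0) & (y > 0)
        if int(ok.sum()) < min_shared:
            rows.append({"run_a": a, "run_b": b, "r_squared": np.nan,
                         "n_shared": int(ok.sum()), "flagged": True,
                         "pair_type": None})
            continue
        r = np.corrcoef(np.log10(x[ok]), np.log10(y[ok]))[0, 1]
        same_age = meta.loc[a, "age_group"] == meta.loc[b, "age_group"]
        same_geno = meta.loc[a, "genotype"] == meta.loc[b, "genotype"]
        kind = ("within_group" if same_age and same_geno
                else "between_genotype" if same_age
                else "between_age")
        rows.append({"run_a": a, "run_b": b, "r_squared": float(r * r),
                     "n_shared": int(ok.sum()), "flagged": False,
                     "pair_type": kind})
    pairs = pd.DataFrame(rows)
    usable = pairs.loc[~pairs["flagged"]]
    summary = {
        kind: float(grp["r_squared"].mean())
        for kind, grp in usable.groupby("pair_type")
    } if len(usable) else {}
    return pairs, summary


# ---------------------------------------------------------------------------
# Differential testing
# ---------------------------------------------------------------------------

def two_group_anova_pvalues(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised one-way two-group ANOVA over rows.

    ``x`` (m x n1) and ``y`` (m x n2) are the two groups' values per
    protein.  Returns ``(F, p, zero_var)`` where ``zero_var`` marks rows
    with no within-group variance but unequal means, for which ``p`` is
    the smallest positive float.
    """
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    gm = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
    ssw = ((x - m1[:, None]) ** 2).sum(axis=1) + ((y - m2[:, None]) ** 2).sum(axis=1)
    df2 = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / df2)
    zero_var = (ssw == 0) & (ssb > 0)
    F = np.where(ssw == 0, 0.0, F)          # identical groups -> F = 0
    p = stats.f.sf(F, 1, df2)
    p = np.where(zero_var, np.finfo(float).tiny, p)
    return F, p, zero_var


def differential_test(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    age_group: str,
    log_transform: bool = True,
    model: str = "per_age",
) -> pd.DataFrame:
    """Dys-vs-WT differential abundance within one age group.

    Per protein: one-way two-group ANOVA on (by default) log-transformed
    abundances of the runs in ``age_group``; zeros get a half-minimum
    pseudo-abundance before the log.  ``fold_change`` is the ratio of
    linear-scale group means (Dys/WT); ``q = min(1, p·m)`` with ``m`` the
    number of proteins tested.  ``model="two_way"`` instead fits genotype,
    age and their interaction on all runs and reports the genotype p-value
    (the fold change stays within the requested age group).

    Returns a DataFrame with columns ``protein, age_group, fold_change,
    p_value, q_value, tier, flags``.
    """
    age_group = str(age_group)
    meta = design.set_index("run_id")
    sel = meta.index[meta["age_group"].astype(str) == age_group]
    sel = [r for r in matrix.columns if r in set(sel)]
    if not sel:
        raise ValueError(f"no runs in age group {age_group!r}")
    sub = matrix[sel]
    geno = meta.loc[sel, "genotype"]
    wt_runs = [r for r in sel if geno[r] == "WT"]
    dys_runs = [r for r in sel if geno[r] == "Dys"]
    if len(wt_runs) < 2 or len(dys_runs) < 2:
        raise ValueError("need >=2 replicates per genotype in the age group")

    nonzero = (sub > 0).any(axis=1)
    n_allzero = int((~nonzero).sum())
    if n_allzero:
        logger.info("differential_test: excluded %d all-zero protein(s)", n_allzero)
    sub = sub.loc[nonzero]

    values = sub.to_numpy(float)
    if log_transform:
        # zeros get a per-protein half-minimum pseudo-abundance
        masked = np.where(values > 0, values, np.inf)
        pseudo = 0.5 * masked.min(axis=1, keepdims=True)
        tested = np.log2(np.where(values > 0, values, pseudo))
    else:
        tested = values
    tested = pd.DataFrame(tested, index=sub.index, columns=sub.columns)

    x = tested[wt_runs].to_numpy()
    y = tested[dys_runs].to_numpy()

    if model == "per_age":
        _, p, zero_var = two_group_anova_pvalues(x, y)
    elif model == "two_way":
        p, zero_var = _two_way_genotype_pvalues(matrix.loc[sub.index], meta,
                                                log_transform)
    else:
        raise ValueError(f"unknown model {model!r}")

    wt_mean = sub[wt_runs].mean(axis=1).to_numpy()
    dys_mean = sub[dys_runs].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(wt_mean > 0, dys_mean / wt_mean, np.inf)

    m = len(sub)
    q = np.minimum(1.0, p * m)
    tier = np.where(q < Q_THRESHOLD, "strong",
                    np.where(p < P_THRESHOLD, "moderate", "none"))
    flags = np.where(zero_var, "zero_within_group_variance", "")
    flags = np.where(np.isinf(fold), np.char.add(flags, ";wt_mean_zero"), flags)

    out = pd.DataFrame({
        "protein": sub.index,
        "age_group": age_group,
        "fold_change": fold,
        "p_value": p,
        "q_value": q,
        "tier": tier,
        "flags": flags,
    }).reset_index(drop=True)
    return out.sort_values(["q_value", "p_value", "protein"],
                           kind="mergesort").reset_index(drop=True)


def _two_way_genotype_pvalues(matrix, meta, log_transform):
    """Genotype main-effect p from a genotype x age two-way ANOVA (type II)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    values = matrix.to_numpy(float)
    if log_transform:
        masked = np.where(values > 0, values, np.inf)
        pseudo = 0.5 * np.where(np.isfinite(masked.min(axis=1, keepdims=True)),
                                masked.min(axis=1, keepdims=True), 1.0)
        values = np.log2(np.where(values > 0, values, pseudo))
    base = pd.DataFrame({
        "genotype": meta.loc[matrix.columns, "genotype"].to_numpy(),
        "age": meta.loc[matrix.columns, "age_group"].astype(str).to_numpy(),
    })
    p = np.empty(len(matrix))
    zero_var = np.zeros(len(matrix), bool)
    for i in range(len(matrix)):
        df = base.assign(y=values[i])
        if df.groupby(["genotype", "age"])["y"].var(ddof=1).fillna(0).eq(0).all():
            means = df.groupby("genotype")["y"].mean()
            if means.nunique() > 1:
                p[i] = np.finfo(float).tiny
                zero_var[i] = True
            else:
                p[i] = 1.0
            continue
        fit = ols("y ~ C(genotype) * C(age)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        p[i] = float(table.loc["C(genotype)", "PR(>F)"])
    return p, zero_var


def significance_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Counts of moderate/strong proteins per age group, split by direction."""
    if len(results) == 0:
        raise ValueError("no differential results to summarise")
    rows = []
    for age, grp in results.groupby("age_group"):
        for tier in ("moderate", "strong"):
            hits = grp[grp["tier"] == tier] if tier == "strong" else \
                grp[grp["tier"].isin(("moderate", "strong"))]
            rows.append({
                "age_group": age,
                "tier": tier,
                "n_proteins": len(hits),
                "n_increased": int((hits["fold_change"] > 1).sum()),
                "n_decreased": int((hits["fold_change"] < 1).sum()),
            })
    return pd.DataFrame(rows)
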