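"""Gene-signature z-score scoring and group comparison by ANCOVA.

An expression matrix (genes x samples, log-scale normalized values) is
standardized per gene across samples; a direction-annotated signature
(+1 induced, -1 repressed) is then scored per sample as the unweighted
mean of direction-weighted z-values.  This follows the common
"pathway-activity score" construction: a sample in which induced genes
are high and repressed genes low scores positive.

Group comparisons use a one-way ANCOVA — the linear model
score ~ group + covariate with an F test on the group term — with the
baseline tumor volume as the default in vivo covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "SignatureScoreResult",
    "zscore_normalize",
    "score_signature",
    "compare_scores_ancova",
    "read_signature",
    "write_signature",
]

# fraction of signature genes that must be present in the matrix
DEFAULT_MIN_SIGNATURE_COVERAGE = 0.5


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression, genes x samples, with annotations."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    groups: pd.Series  # sample -> group label
    covariate: pd.Series | None = None  # sample -> numeric covariate

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group annotation: {sorted(missing)[:5]}")


@dataclass
class GeneSignature:
    """Direction-annotated gene set: +1 induced, -1 repressed."""

    directions: pd.Series  # gene id -> +1 / -1

    def __post_init__(self) -> None:
        if len(self.directions) == 0:
            raise ValueError("signature must be non-empty")
        bad = set(np.unique(self.directions)) - {-1, 1}
        if bad:
            raise ValueError(f"directions must be +1 or -1, got {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.directions.index

    def flipped(self) -> "GeneSignature":
        return GeneSignature(directions=-self.directions)


def zscore_normalize(
    matrix: ExpressionMatrix, population_sd: bool = True
) -> ExpressionMatrix:
    """Standardize each gene across samples: (x - mean) / SD.

    Constant genes (zero SD) are dropped with a warning.  The default SD
    convention divides by n (population SD); set ``population_sd=False``
    for the n-1 sample convention.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("z-scoring requires >= 2 samples")
    ddof = 0 if population_sd else 1
    vals = matrix.values
    sd = vals.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        dropped = list(vals.index[constant])
        warnings.warn(
            f"dropping {len(dropped)} constant gene(s) from z-matrix: {dropped[:5]}",
            UserWarning,
            stacklevel=2,
        )
        vals = vals.loc[~constant]
        sd = sd.loc[~constant]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(values=z, groups=matrix.groups, covariate=matrix.covariate)


def score_signature(
    zmatrix: ExpressionMatrix,
    signature: GeneSignature,
    min_coverage: float = DEFAULT_MIN_SIGNATURE_COVERAGE,
) -> pd.Series:
    """Per-sample signature score: mean over signature genes of direction * z.

    Genes absent from the matrix are logged and skipped; if fewer than
    ``min_coverage`` of the signature remains, scoring is refused.
    """
    present = signature.genes.intersection(zmatrix.values.index)
    if len(present) == 0:
        raise ValueError("no signature genes present in the expression matrix")
    coverage = len(present) / len(signature.genes)
    missing = signature.genes.difference(zmatrix.values.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix: "
            f"{list(missing[:5])}",
            UserWarning,
            stacklevel=2,
        )
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.0%} of signature genes present; "
            f"minimum coverage is {min_coverage:.0%}"
        )
    sub = zmatrix.values.loc[present]
    weighted = sub.mul(signature.directions.loc[present], axis=0)
    scores = weighted.mean(axis=0)
    scores.name = "signature_score"
    return scores


@dataclass
class SignatureScoreResult:
    scores: pd.Series
    group_means: pd.Series
    group_se: pd.Series
    delta: float  # treated minus control mean, for two-group designs
    p_value: float


def compare_scores_ancova(
    scores: pd.Series,
    groups: pd.Series,
    covariate: pd.Series | None = None,
) -> SignatureScoreResult:
    """One-way ANCOVA on signature scores: score ~ group + covariate.

    F test for the group term from the linear model.  A missing or
    constant covariate degrades gracefully to one-way ANOVA.  Requires
    >= 2 groups with >= 2 samples each.
    """
    groups = groups.loc[scores.index]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("ANCOVA requires >= 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with < 2 samples: {small}")

    group_dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
    use_cov = covariate is not None
    if use_cov:
        cov = pd.to_numeric(covariate.loc[scores.index])
        if cov.std() == 0:
            use_cov = False  # constant covariate carries no information
    X_parts = [group_dummies]
    if use_cov:
        X_parts.append(cov.rename("covariate").to_frame())
    X_full = sm.add_constant(pd.concat(X_parts, axis=1))
    full = sm.OLS(np.asarray(scores, dtype=float), np.asarray(X_full, dtype=float)).fit()
    # reduced model drops the group dummies; F test on the group term
    n = len(scores)
    if use_cov:
        X_red = np.column_stack([np.ones(n), np.asarray(cov, dtype=float)])
    else:
        X_red = np.ones((n, 1))
    reduced = sm.OLS(np.asarray(scores, dtype=float), X_red).fit()
    df_num = group_dummies.shape[1]
    df_den = int(full.df_resid)
    f_stat = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(_st.f.sf(f_stat, df_num, df_den))

    means = scores.groupby(groups).mean()
    se = scores.groupby(groups).sem()
    labels = sorted(means.index)
    delta = float(means[labels[-1]] - means[labels[0]]) if len(labels) == 2 else np.nan
    return SignatureScoreResult(
        scores=scores, group_means=means, group_se=se, delta=delta, p_value=p
    )


def read_signature(path) -> GeneSignature:
    """Read a two-column text file (gene, direction) into a signature."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "direction"} <= set(df.columns):
        raise ValueError("signature file requires columns (gene, direction)")
    return GeneSignature(
        directions=pd.Series(
            df["direction"].astype(int).to_numpy(), index=df["gene"].astype(str)
        )
    )


def write_signature(signature: GeneSignature, path) -> None:
    pd.DataFrame(
        {"gene": signature.genes, "direction": signature.directions.to_numpy()}
    ).to_csv(path, sep="\t", index=False)
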