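"""Design-matrix construction for the grouped penalized logistic model.

Turns a :class:`~leadlasso.simulate.SurveyDataset` into a binary response
``y`` (1 = BLL >= 10 µg/dL) and a dummy-expanded design matrix ``X`` whose
columns are partitioned into covariate groups: each k-category questionnaire
item contributes one group of k-1 indicators (first category = reference),
each continuous anthropometric a singleton group.  Model fits are
complete-case: rows missing the BLL or any model covariate are dropped.

Group standardization orthonormalizes each centered group block so that
``block.T @ block / n == I``; the closed-form group soft-threshold update of
the group-descent solver is exact under this transform.  The transform is
recorded so fitted coefficients map back to the original covariate scale
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .codebook import Codebook
from .simulate import BLL_THRESHOLD, SurveyDataset


class EncodingError(ValueError):
    """Illegal category or otherwise unencodable record."""


class GroupRankError(ValueError):
    """A covariate group is rank-deficient after centering."""


def classify_bll(bll, threshold: float = BLL_THRESHOLD):
    """1 if BLL >= threshold (inclusive), else 0; vectorized."""
    arr = np.asarray(bll, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing BLL cannot be classified; exclude upstream")
    if (arr <= 0).any():
        raise ValueError("BLL must be positive")
    out = (arr >= threshold).astype(int)
    return out if out.ndim else int(out)


@dataclass
class Standardization:
    """Per-column centers plus per-group orthonormalizing transforms R_g.

    Standardized block = (X_g - centers_g) @ R_g.  A standardized-scale
    coefficient vector b_g maps back as beta_g = R_g @ b_g, and the intercept
    as beta_0 = b_0 - centers @ beta.
    """

    centers: np.ndarray
    transforms: list  # one (df_g, df_g) array per group

    def to_original(self, intercept_std: float, beta_std: np.ndarray, slices) -> tuple[float, np.ndarray]:
        beta = np.empty_like(beta_std)
        for g, sl in enumerate(slices):
            beta[sl] = self.transforms[g] @ beta_std[sl]
        b0 = float(intercept_std - self.centers @ beta)
        return b0, beta


@dataclass
class EncodedDataset:
    """Binary response, grouped design matrix, and group metadata."""

    y: np.ndarray
    X: np.ndarray
    group_index: np.ndarray  # per-column group id, 0..G-1, contiguous
    group_names: list
    df: np.ndarray  # per-group column counts
    column_names: list
    row_ids: np.ndarray
    standardization: Standardization | None = None

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), len(self.column_names)):
            raise ValueError("X shape inconsistent with y / column names")
        if int(self.df.sum()) != self.X.shape[1]:
            raise ValueError("group df must sum to the number of columns")
        # groups must be contiguous blocks in column order
        seen = []
        for g in self.group_index:
            if not seen or seen[-1] != g:
                seen.append(g)
        if len(seen) != len(set(seen)):
            raise ValueError("columns of one group must be contiguous")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def rescale(self) -> np.ndarray:
        """Penalty weights s(df_g) = sqrt(df_g)."""
        return np.sqrt(self.df.astype(float))

    @property
    def slices(self) -> list:
        out, start = [], 0
        for k in self.df:
            out.append(slice(start, start + int(k)))
            start += int(k)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "y", self.y)
        return df


def encode_dummies(
    dataset: SurveyDataset,
    codebook: Codebook | None = None,
    threshold: float = BLL_THRESHOLD,
    drop_constant_columns: bool = False,
) -> EncodedDataset:
    """Dummy-expand a survey into a grouped design matrix (complete cases).

    With ``drop_constant_columns=True``, dummy columns that are constant in
    the (sub)sample, or linearly dependent within their group after centering
    (e.g. the reference category is unobserved, so the remaining dummies sum
    to one), are dropped; a group vanishes entirely if nothing informative
    remains.  This keeps complete-case subsets and resampling replicates
    encodable; the default is strict.
    """
    codebook = codebook or dataset.codebook
    df = dataset.data

    needed = ["bll"] + [e.name for e in codebook]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise EncodingError(f"dataset lacks columns {missing_cols}")

    # validate categories before dropping rows so errors name the record
    for entry in codebook:
        if entry.kind == "continuous":
            continue
        vals = df[entry.name]
        bad = vals.notna() & ~vals.isin(entry.categories)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise EncodingError(
                f"record {df['child_id'].iloc[i]}: unknown category "
                f"{vals.iloc[i]!r} for field {entry.name!r}"
            )

    complete = df[needed].notna().all(axis=1)
    sub = df.loc[complete]
    if len(sub) == 0:
        raise EncodingError("no complete-case records")

    y = classify_bll(sub["bll"].to_numpy(dtype=float), threshold)

    blocks, col_names, group_names, dfs = [], [], [], []
    for entry in codebook:
        if entry.kind == "continuous":
            block = sub[entry.name].to_numpy(dtype=float)[:, None]
            names = [entry.name]
        else:
            vals = sub[entry.name].to_numpy()
            block = np.column_stack(
                [(vals == cat).astype(float) for cat in entry.categories[1:]]
            )
            names = [f"{entry.name}[{cat}]" for cat in entry.categories[1:]]
        if drop_constant_columns:
            keep = _independent_columns(block)
            if not keep:
                continue
            block = block[:, keep]
            names = [names[j] for j in keep]
        blocks.append(block)
        col_names.extend(names)
        group_names.append(entry.name)
        dfs.append(block.shape[1])

    X = np.concatenate(blocks, axis=1)
    group_index = np.repeat(np.arange(len(group_names)), dfs)
    return EncodedDataset(
        y=np.asarray(y, dtype=int),
        X=X,
        group_index=group_index,
        group_names=group_names,
        df=np.asarray(dfs, dtype=int),
        column_names=col_names,
        row_ids=sub["child_id"].to_numpy(),
    )


def _independent_columns(block: np.ndarray, rtol: float = 1e-8) -> list:
    """Indices of a maximal linearly independent column subset after centering
    (pivoted QR); preserves original column order."""
    centered = block - block.mean(axis=0)
    scale = np.abs(centered).max()
    if scale == 0.0:
        return []
    from scipy.linalg import qr

    _, R, piv = qr(centered, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > rtol * diag[0]).sum()) if diag[0] > rtol * scale else 0
    return sorted(piv[:rank])


def reduce_collinear(encoded: EncodedDataset) -> tuple["EncodedDataset", np.ndarray]:
    """Drop columns constant or linearly dependent within their group.

    Returns the reduced dataset plus the kept column indices (for applying a
    fitted model to other rows of the original design).  Used on data subsets
    (CV training splits, resampling replicates) where rare categories may be
    unobserved.
    """
    keep_cols: list[int] = []
    group_names, dfs = [], []
    for g, sl in enumerate(encoded.slices):
        keep = _independent_columns(encoded.X[:, sl])
        if not keep:
            continue
        keep_cols.extend(sl.start + j for j in keep)
        group_names.append(encoded.group_names[g])
        dfs.append(len(keep))
    keep_idx = np.asarray(keep_cols, dtype=int)
    reduced = EncodedDataset(
        y=encoded.y,
        X=encoded.X[:, keep_idx],
        group_index=np.repeat(np.arange(len(group_names)), dfs),
        group_names=group_names,
        df=np.asarray(dfs, dtype=int),
        column_names=[encoded.column_names[j] for j in keep_idx],
        row_ids=encoded.row_ids,
    )
    return reduced, keep_idx


def standardize_groups(encoded: EncodedDataset) -> EncodedDataset:
    """Center columns and orthonormalize each group block.

    For each group g with centered block ``Xc_g``, computes the upper-
    triangular ``R_g`` with ``(Xc_g @ R_g).T @ (Xc_g @ R_g) / n = I`` from the
    Cholesky factor of the Gram matrix; a singular Gram matrix raises
    :class:`GroupRankError` naming the group.
    """
    if encoded.standardization is not None:
        return encoded
    n = encoded.n
    centers = encoded.X.mean(axis=0)
    Xc = encoded.X - centers
    Xs = np.empty_like(Xc)
    transforms = []
    for g, sl in enumerate(encoded.slices):
        gram = Xc[:, sl].T @ Xc[:, sl] / n
        try:
            L = cholesky(gram, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover - scipy raises LinAlgError
            raise GroupRankError(
                f"group {encoded.group_names[g]!r} is rank-deficient after centering"
            ) from e
        except Exception as e:
            raise GroupRankError(
                f"group {encoded.group_names[g]!r} is rank-deficient after centering"
            ) from e
        # R = L^{-T}: R^T gram R = I
        R = solve_triangular(L, np.eye(L.shape[0]), lower=True).T
        Xs[:, sl] = Xc[:, sl] @ R
        transforms.append(R)
    return replace(
        encoded, X=Xs, standardization=Standardization(centers=centers, transforms=transforms)
    )
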