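"""Forward-selection Haley-Knott regression under three model families.

Haley-Knott regression is ordinary least squares of the phenotype on the
expected allele dosage at a marker.  Three model kinds are supported:

* ``biparental`` — one family, linkage (parent-of-origin) codes;
* ``joint_linkage`` — multiparental, a marker's effect is a separate
  coefficient for each included family in which it segregates (nested
  effects), with family as a fixed covariate;
* ``gwas`` — multiparental, one coefficient per marker across all families
  on the shared allele coding, with family as a fixed covariate.

Selection statistic: the partial F test of the added term block.  Nested
blocks carry one df per segregating family, so F handles the differing df
of GWAS (1) and joint-linkage (k) candidates; the permutation threshold is
computed on the same statistic, keeping the comparison internally
consistent.  A p-value based variant (select by smallest p, thresholded on
-log10 p) is available through ``ModelSpec.select_by``.

Genome-wide significance comes from permutations of phenotypes within each
family separately: the empirical (1 - alpha) quantile (type-1 /
order-statistic rule) of the per-permutation genome-wide maximum statistic.
The null is computed once against the base (family-covariates only) model
and reused at every forward step; per-step recomputation is available
behind ``threshold_per_step``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .encode import GwasDataset, LinkageDataset

_EPS = 1e-9

MODEL_KINDS = ("biparental", "joint_linkage", "gwas")


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """A mapping model: kind, family subset, trait, and scan parameters."""

    kind: str
    families: tuple
    trait: str
    alpha: float = 0.01
    n_perm: int = 1000
    seed: int = 0
    max_steps: int = 10
    select_by: str = "fstat"          # "fstat" | "pvalue"
    threshold_per_step: bool = False

    def __post_init__(self):
        object.__setattr__(self, "families", tuple(self.families))
        if self.kind not in MODEL_KINDS:
            raise MappingError(f"unknown model kind {self.kind!r}")
        if self.kind == "biparental" and len(self.families) != 1:
            raise MappingError("biparental models take exactly one family")
        if not self.families:
            raise MappingError("at least one family is required")
        if self.select_by not in ("fstat", "pvalue"):
            raise MappingError(f"unknown select_by {self.select_by!r}")
        if not (0 < self.alpha <= 1):
            raise MappingError("alpha must be in (0, 1]")


# ---------------------------------------------------------------------------
# Alignment of genotypes and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class MappingData:
    """Model-ready view: one trait, one family subset, aligned rows."""

    codes: np.ndarray        # (n, m); NaN only at family-masked linkage cells
    family: np.ndarray
    families: tuple
    seg: np.ndarray          # (k, m) bool: candidate-eligible per family
    snp_map: "SnpMap"
    kind: str
    y: np.ndarray
    line_id: np.ndarray

    @property
    def n_lines(self):
        return self.y.size

    @property
    def n_snps(self):
        return self.codes.shape[1]

    def family_rows(self, fam):
        return np.flatnonzero(self.family == fam)


def align(dataset, phenotypes: pd.DataFrame, model: ModelSpec) -> MappingData:
    """Subset a dataset to the model's families and attach the trait vector.

    Lines without a (non-missing) phenotype record are dropped.
    """
    matrix = dataset.matrix
    if model.trait not in phenotypes.columns:
        raise MappingError(f"trait {model.trait!r} not in phenotype table")
    for fam in model.families:
        if fam not in matrix.families:
            raise MappingError(f"family {fam!r} not present in dataset")
    expected = LinkageDataset if model.kind in ("biparental", "joint_linkage") else GwasDataset
    if not isinstance(dataset, expected):
        raise MappingError(f"model kind {model.kind!r} requires a {expected.__name__}")
    pheno = phenotypes.set_index("line_id")[model.trait]
    rows, y = [], []
    for i, (lid, fam) in enumerate(zip(matrix.line_id, matrix.family)):
        if fam not in model.families:
            continue
        v = pheno.get(lid, np.nan)
        if np.isnan(v):
            continue
        rows.append(i)
        y.append(float(v))
    if not rows:
        raise MappingError("no lines with phenotypes for the requested families")
    rows = np.array(rows)
    codes = matrix.codes[rows]
    family = matrix.family[rows]
    m = matrix.snp_map.n_snps
    seg = np.zeros((len(model.families), m), dtype=bool)
    for fi, fam in enumerate(model.families):
        sub = codes[family == fam]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            varies = np.nanmax(sub, axis=0) > np.nanmin(sub, axis=0)
        if isinstance(dataset, LinkageDataset):
            seg[fi] = dataset.seg[fam] & varies
        else:
            seg[fi] = varies
    return MappingData(codes, family, model.families, seg, matrix.snp_map,
                       model.kind, np.array(y), matrix.line_id[rows])


# ---------------------------------------------------------------------------
# Linear algebra
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    beta: np.ndarray        # NaN for dropped (dependent) columns
    rss: float
    df_resid: int
    kept: np.ndarray        # bool per column
    se: np.ndarray = None   # standard errors; NaN for dropped columns


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Greedy left-to-right selection of linearly independent columns."""
    n, p = X.shape
    Q = np.empty((n, 0))
    kept = np.zeros(p, dtype=bool)
    for j in range(p):
        col = X[:, j]
        r = col - Q @ (Q.T @ col) if Q.shape[1] else col.copy()
        r = r - Q @ (Q.T @ r) if Q.shape[1] else r   # reorthogonalize
        nrm = np.linalg.norm(r)
        if nrm > tol * max(1.0, np.linalg.norm(col)):
            Q = np.hstack([Q, (r / nrm)[:, None]])
            kept[j] = True
    return kept


def fit_linear(y: np.ndarray, X: np.ndarray) -> FitResult:
    """Least squares of y on the columns of X.

    Rank-deficient designs are resolved by dropping dependent columns
    deterministically (left to right); dropped coefficients are NaN.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    kept = _independent_columns(X)
    Xk = X[:, kept]
    df_resid = y.size - Xk.shape[1]
    if df_resid <= 0:
        raise MappingError("zero residual degrees of freedom")
    beta_k, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta_k
    rss = float(resid @ resid)
    beta = np.full(X.shape[1], np.nan)
    beta[kept] = beta_k
    se = np.full(X.shape[1], np.nan)
    sigma2 = rss / df_resid
    se[kept] = np.sqrt(np.diag(np.linalg.pinv(Xk.T @ Xk)) * sigma2)
    return FitResult(beta, rss, int(df_resid), kept, se)


def adjusted_r2(r2: float, n_obs: int, n_params: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1) with p non-intercept parameters."""
    if n_obs <= n_params + 1:
        raise MappingError("adjusted R^2 undefined: n <= p + 1")
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_params - 1)


def _orth_basis(X: np.ndarray) -> np.ndarray:
    kept = _independent_columns(X)
    Q, _ = np.linalg.qr(X[:, kept])
    return Q


def _base_columns(data: MappingData) -> np.ndarray:
    """Intercept plus one indicator per family beyond the first."""
    cols = [np.ones(data.n_lines)]
    for fam in data.families[1:]:
        cols.append((data.family == fam).astype(np.float64))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Candidate terms
# ---------------------------------------------------------------------------

def candidate_term(snp: int, model: ModelSpec, data: MappingData):
    """Design columns for adding one SNP to the model.

    GWAS: a single 0-2 dosage column across all lines.  Joint linkage /
    biparental: one column per included family in which the SNP segregates
    (the family's codes, zero elsewhere).  Returns ``(columns, families)``
    where ``families`` is empty-string-labelled for the combined GWAS
    column.
    """
    if data.kind == "gwas":
        if not data.seg[:, snp].any():
            raise MappingError(f"SNP {snp} is monomorphic in every included family")
        return data.codes[:, [snp]].copy(), ("combined",)
    fams = [f for fi, f in enumerate(data.families) if data.seg[fi, snp]]
    if not fams:
        raise MappingError(f"SNP {snp} is masked in all included families")
    cols = np.zeros((data.n_lines, len(fams)))
    for j, fam in enumerate(fams):
        rows = data.family_rows(fam)
        cols[rows, j] = data.codes[rows, snp]
    return cols, tuple(fams)


@dataclass
class _Candidates:
    """Residualized candidate terms for a fixed base design."""

    kind: str
    active: np.ndarray           # (m,) testable at all
    df1: np.ndarray              # (m,) block df
    # gwas
    xres: np.ndarray | None = None
    norms: np.ndarray | None = None
    # nested
    mres: list = field(default_factory=list)     # per family (n, m)
    fam_active: np.ndarray | None = None         # (k, m)
    ginv: np.ndarray | None = None               # (m, k, k)


def _prepare_candidates(data: MappingData, Q: np.ndarray) -> _Candidates:
    n, m = data.codes.shape
    if data.kind == "gwas":
        C = data.codes
        xres = C - Q @ (Q.T @ C)
        norms = np.einsum("ij,ij->j", xres, xres)
        active = data.seg.any(axis=0) & (norms > _EPS * n)
        return _Candidates("gwas", active, np.ones(m), xres=xres, norms=norms)
    k = len(data.families)
    mres, fam_active = [], np.zeros((k, m), dtype=bool)
    for fi, fam in enumerate(data.families):
        rows = data.family_rows(fam)
        M = np.zeros((n, m))
        sub = data.codes[rows]
        has_nan = np.isnan(sub).any(axis=0)
        M[rows] = np.nan_to_num(sub)
        Mres = M - Q @ (Q.T @ M)
        nrm = np.einsum("ij,ij->j", Mres, Mres)
        ok = data.seg[fi] & ~has_nan & (nrm > _EPS * n)
        Mres[:, ~ok] = 0.0
        mres.append(Mres)
        fam_active[fi] = ok
    df1 = fam_active.sum(axis=0).astype(np.float64)
    active = df1 > 0
    G = np.zeros((m, k, k))
    for fi in range(k):
        for gj in range(fi, k):
            dots = np.einsum("ij,ij->j", mres[fi], mres[gj])
            G[:, fi, gj] = dots
            G[:, gj, fi] = dots
    # inactive dimensions become identity rows so the batched inverse is safe
    for fi in range(k):
        off = ~fam_active[fi]
        G[off, fi, :] = 0.0
        G[off, :, fi] = 0.0
        G[off, fi, fi] = 1.0
    G[~active] = np.eye(k)
    ginv = np.linalg.inv(G)
    return _Candidates("nested", active, df1, mres=mres,
                       fam_active=fam_active, ginv=ginv)


def _delta_rss(cand: _Candidates, Yres: np.ndarray) -> np.ndarray:
    """RSS reduction per (SNP, response column); Yres is (n, B)."""
    if cand.kind == "gwas":
        T = cand.xres.T @ Yres                     # (m, B)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(cand.active[:, None], T * T / cand.norms[:, None], 0.0)
    b = np.stack([M.T @ Yres for M in cand.mres])  # (k, m, B)
    tmp = np.einsum("mfg,gmb->fmb", cand.ginv, b, optimize=True)
    return np.einsum("fmb,fmb->mb", b, tmp, optimize=True)


def _stat_from_delta(delta, rss0, df1, df_resid_base, select_by):
    """F (or -log10 p) per SNP; df_resid_base is the base-model residual df."""
    df2 = df_resid_base - df1
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (delta / df1) / np.maximum(rss0 - delta, 0.0) * df2
        pval = sstats.f.sf(fstat, df1, np.maximum(df2, 1e-12))
    if select_by == "pvalue":
        with np.errstate(divide="ignore"):
            stat = -np.log10(np.maximum(pval, 0.0))
    else:
        stat = fstat
    return fstat, pval, stat


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-SNP partial test of adding that SNP to the current model."""

    fstat: np.ndarray
    pvalue: np.ndarray
    df1: np.ndarray
    tested: np.ndarray
    stat: np.ndarray        # the selection statistic (F or -log10 p)
    rss0: float
    df_resid: int


def scan(data: MappingData, model: ModelSpec, selected_blocks=(),
         exclude=()) -> ScanResult:
    """Partial-F scan of every scannable SNP against the current model.

    ``selected_blocks`` are the design-column blocks of previously selected
    SNPs (always refit jointly); ``exclude`` lists SNP indices to skip.
    """
    base = _base_columns(data)
    if selected_blocks:
        base = np.hstack([base] + [b for b, _ in selected_blocks])
    Q = _orth_basis(base)
    cand = _prepare_candidates(data, Q)
    yres = data.y - Q @ (Q.T @ data.y)
    rss0 = float(yres @ yres)
    df_resid = data.n_lines - Q.shape[1]
    delta = _delta_rss(cand, yres[:, None])[:, 0]
    fstat, pval, stat = _stat_from_delta(delta, rss0, cand.df1, df_resid,
                                         model.select_by)
    tested = cand.active & (df_resid - cand.df1 > 0)
    if len(exclude):
        tested[np.asarray(list(exclude), dtype=int)] = False
    fstat[~tested] = np.nan
    pval[~tested] = np.nan
    stat[~tested] = -np.inf
    return ScanResult(fstat, pval, cand.df1, tested, stat, rss0, df_resid)


# ---------------------------------------------------------------------------
# Permutation threshold
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Genome-wide maximum statistics under within-family permutation."""

    max_stats: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    seed: int


def permutation_rng(seed: int, i: int) -> np.random.Generator:
    """Deterministic substream for permutation ``i`` (replayable)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def _permuted_phenotypes(data: MappingData, n_perm: int, seed: int) -> np.ndarray:
    """(n, n_perm) matrix: phenotypes shuffled independently within family."""
    Y = np.empty((data.n_lines, n_perm))
    fam_rows = [data.family_rows(f) for f in data.families]
    for i in range(n_perm):
        rng = permutation_rng(seed, i)
        col = Y[:, i]
        for rows in fam_rows:
            col[rows] = data.y[rows][rng.permutation(rows.size)]
    return Y


def empirical_threshold(max_stats: np.ndarray, alpha: float) -> float:
    """Empirical (1-alpha) threshold: the (n - floor(n*alpha) + 1)-th order
    statistic, i.e. the floor(n*alpha)-th largest maximum (1000 permutations
    at alpha=0.01 -> the 10th largest).  A fresh exchangeable draw exceeds
    it with probability floor(n*alpha)/(n+1), which is alpha to within
    discreteness; alpha=1 degenerates to the minimum."""
    n = max_stats.size
    k = min(n, max(1, n - math.floor(n * alpha) + 1))
    return float(np.sort(max_stats)[k - 1])


#: permutations processed per work unit; fixed so results are independent
#: of the thread count
_PERM_CHUNK = 256


def permutation_threshold(data: MappingData, model: ModelSpec,
                          selected_blocks=(), threads: int = 1) -> PermutationNull:
    """Null distribution of the genome-wide maximum scan statistic.

    Phenotype values are shuffled independently within each family (family
    labels and genotypes fixed); each permutation records the maximum
    statistic over all scannable SNPs; the threshold is the empirical
    (1 - alpha) order-statistic quantile.  ``threads`` parallelizes over
    fixed-size permutation chunks, so the result does not depend on it.
    """
    if model.n_perm < 20 / model.alpha:
        warnings.warn(
            f"n_perm={model.n_perm} is small for alpha={model.alpha}; "
            "the quantile estimate will be unstable", stacklevel=2)
    base = _base_columns(data)
    if selected_blocks:
        base = np.hstack([base] + [b for b, _ in selected_blocks])
    Q = _orth_basis(base)
    cand = _prepare_candidates(data, Q)
    Y = _permuted_phenotypes(data, model.n_perm, model.seed)
    df_resid = data.n_lines - Q.shape[1]
    tested = cand.active & (df_resid - cand.df1 > 0)

    def _chunk_max(sl):
        Yres = Y[:, sl] - Q @ (Q.T @ Y[:, sl])
        rss0 = np.einsum("ij,ij->j", Yres, Yres)
        delta = _delta_rss(cand, Yres)
        _, _, stat = _stat_from_delta(delta, rss0[None, :], cand.df1[:, None],
                                      df_resid, model.select_by)
        stat[~tested] = -np.inf
        return stat.max(axis=0)

    chunks = [slice(i, min(i + _PERM_CHUNK, model.n_perm))
              for i in range(0, model.n_perm, _PERM_CHUNK)]
    if threads > 1 and len(chunks) > 1:
        from concurrent.futures import ThreadPoolExecutor
        with ThreadPoolExecutor(max_workers=threads) as pool:
            parts = list(pool.map(_chunk_max, chunks))
    else:
        parts = [_chunk_max(sl) for sl in chunks]
    max_stats = np.concatenate(parts)
    return PermutationNull(max_stats, empirical_threshold(max_stats, model.alpha),
                           model.alpha, model.n_perm, model.seed)


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedQtl:
    step: int
    snp_index: int
    snp_id: str
    chrom: str
    pos_bp: int
    fstat: float
    pvalue: float
    df: int
    effects: dict            # family -> slope (or {"combined": slope})
    seg_state: dict          # family -> 0/1/2 fixation/segregation code
    effect_se: dict = field(default_factory=dict)


@dataclass
class QtlModelResult:
    """Final forward-regression model for one (model, trait) combination."""

    model: ModelSpec
    selected: list
    threshold: float
    null: PermutationNull | None
    r2: float
    r2_adj: float
    n_lines: int
    family_coefs: dict
    scans: list = field(default_factory=list)   # per-step ScanResult profiles

    @property
    def n_qtl(self) -> int:
        return len(self.selected)


def _seg_state(data: MappingData, snp: int) -> dict:
    out = {}
    for fi, fam in enumerate(data.families):
        sub = data.codes[data.family_rows(fam), snp]
        sub = sub[~np.isnan(sub)]
        if sub.size and sub.max() == sub.min():
            out[fam] = 0 if sub[0] == 0.0 else (2 if sub[0] == 2.0 else 1)
        else:
            out[fam] = 1
    return out


def forward_select(dataset, phenotypes: pd.DataFrame, model: ModelSpec,
                   threshold: float | None = None, threads: int = 1) -> QtlModelResult:
    """Forward Haley-Knott regression with a permutation threshold.

    Iteratively adds the SNP with the largest scan statistic while it
    strictly exceeds the threshold, refitting all effects jointly after
    each addition.  Exactly equal statistics are broken toward the smallest
    (chromosome, position).  ``threshold`` overrides the permutation null
    (useful for oracle tests); the permutation null is otherwise computed
    once against the base model unless ``model.threshold_per_step``.
    """
    data = align(dataset, phenotypes, model)
    null = None
    if threshold is None:
        null = permutation_threshold(data, model, threads=threads)
        thr = null.threshold
    else:
        thr = float(threshold)
    selected_blocks, selected, taken, scans = [], [], [], []
    for step in range(1, model.max_steps + 1):
        if model.threshold_per_step and threshold is None and selected_blocks:
            null_step = permutation_threshold(data, model, selected_blocks,
                                              threads=threads)
            thr = null_step.threshold
        sc = scan(data, model, selected_blocks, exclude=taken)
        scans.append(sc)
        if not sc.tested.any():
            break
        best = int(np.argmax(sc.stat))   # map order = (chrom, pos); first wins ties
        if not sc.stat[best] > thr:
            break
        cols, fams = candidate_term(best, model, data)
        selected_blocks.append((cols, fams))
        taken.append(best)
        smap = data.snp_map
        selected.append(SelectedQtl(
            step, best, str(smap.snp_id[best]), str(smap.chrom[best]),
            int(smap.pos_bp[best]), float(sc.fstat[best]), float(sc.pvalue[best]),
            int(sc.df1[best]), {}, _seg_state(data, best),
        ))
    return _finalize(data, model, selected, selected_blocks, thr, null, scans)


def _finalize(data, model, selected, selected_blocks, thr, null, scans=()) -> QtlModelResult:
    base = _base_columns(data)
    X = np.hstack([base] + [b for b, _ in selected_blocks]) if selected_blocks else base
    fit = fit_linear(data.y, X)
    tss = float(np.sum((data.y - data.y.mean()) ** 2))
    r2 = 1.0 - fit.rss / tss if tss > 0 else 0.0
    n_params = int(fit.kept.sum()) - 1          # excluding the intercept
    r2a = adjusted_r2(r2, data.n_lines, n_params)
    family_coefs = {data.families[0]: 0.0}
    for i, fam in enumerate(data.families[1:], start=1):
        family_coefs[fam] = float(fit.beta[i])
    off = base.shape[1]
    for sq, (cols, fams) in zip(selected, selected_blocks):
        sq.effects = {fam: float(fit.beta[off + j]) for j, fam in enumerate(fams)}
        sq.effect_se = {fam: float(fit.se[off + j]) for j, fam in enumerate(fams)}
        off += cols.shape[1]
    return QtlModelResult(model, selected, float(thr), null, float(r2),
                          float(r2a), data.n_lines, family_coefs, list(scans))


def estimate_effects(result: QtlModelResult) -> pd.DataFrame:
    """Per-QTL effect table: additive slope per allele copy.

    Nested models report one column per family, with "NS" where the SNP
    does not segregate in that family; GWAS models report the combined
    slope plus a per-family segregation-state code (0 = fixed reference,
    1 = segregating, 2 = fixed alternative).
    """
    rows = []
    for sq in result.selected:
        row = {"step": sq.step, "snp_id": sq.snp_id, "chrom": sq.chrom,
               "pos_bp": sq.pos_bp, "fstat": sq.fstat}
        if result.model.kind == "gwas":
            row["combined"] = sq.effects.get("combined", np.nan)
            for fam in result.model.families:
                row[f"state_{fam}"] = sq.seg_state.get(fam, 1)
        else:
            for fam in result.model.families:
                row[fam] = sq.effects.get(fam, "NS")
        rows.append(row)
    return pd.DataFrame(rows)
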