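"""Single-step whole-genome regression with genotyped and nongenotyped animals.

Model (marker-effects form):

    y = 1 mu + Z J mu_g + Z M alpha + U eps + e

where M stacks the imputed covariates of nongenotyped individuals,
``Mhat_n = Ang Agg^{-1} Mg``, over the observed covariates ``Mg``; J is the
covariate of the founder genotypic mean mu_g (−1 for genotyped
individuals, ``Ang Agg^{-1} (−1)`` for nongenotyped ones); and eps is the
imputation residual of nongenotyped individuals with prior variance
``(Ann − Ang Agg^{-1} Agn) sigma2_g``, whose inverse is exactly the
nn-block of A^{-1} divided by sigma2_g.

With a Gaussian prior on every marker effect (BayesC with pi = 0) and
fixed variances the posterior mean is the solution of a ridge-type mixed
model system, so two routes are provided: an exact sparse solve of the
mixed-model equations (``method="mme"``) and single-site Gibbs sampling
(``method="gibbs"``); they agree within Monte Carlo error.

Model variants differ in whether J is fitted and how covariates are
centered: J/N (uncentered, with/without J), JC/C (whole matrix of
observed + imputed covariates centered), JC*/C* (only the observed
covariates centered by their own means, the single-step GBLUP
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as dla
from scipy import sparse
from scipy.sparse.linalg import splu

from .pedigree import RelationshipOperator
from .simulation import StudyDataset, substream

__all__ = [
    "ModelSpec",
    "DesignSystem",
    "ModelFit",
    "VARIANTS",
    "compute_J_covariate",
    "impute_marker_covariates",
    "apply_centering",
    "build_design",
    "solve_mme",
    "gibbs_bayesc0",
    "compute_gebv",
    "fit_single_step",
]

#: variant label -> (fit_J, centering mode)
VARIANTS = {
    "J": (True, "none"),
    "N": (False, "none"),
    "JC": (True, "all_covariates"),
    "C": (False, "all_covariates"),
    "JCstar": (True, "observed_only"),
    "Cstar": (False, "observed_only"),
}

CENTERING_MODES = ("none", "all_covariates", "observed_only")


class SingularModelError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Fitting choices for one single-step analysis.

    Variances are fixed at their known simulation values (no re-estimation);
    ``marker_variance_rule`` sets the per-marker prior variance: ``"sum2pq"``
    uses sigma2_g / sum_j 2 p_j (1-p_j) with allele frequencies from the
    observed genotypes of the fitted panel, ``"per_marker"`` uses
    sigma2_g / m.
    """

    fit_J: bool = True
    centering: str = "none"
    pi: float = 0.0
    chain_length: int = 50_000
    burn_in: int = 5_000
    seed: int = 0
    marker_variance_rule: str = "sum2pq"

    def __post_init__(self):
        if self.centering not in CENTERING_MODES:
            raise ValueError(f"centering must be one of {CENTERING_MODES}")
        if self.pi != 0.0:
            raise NotImplementedError("only pi = 0 (Gaussian prior on every marker)")
        if self.marker_variance_rule not in ("sum2pq", "per_marker"):
            raise ValueError("marker_variance_rule must be 'sum2pq' or 'per_marker'")

    @classmethod
    def from_variant(cls, variant: str, **kwargs) -> "ModelSpec":
        try:
            fit_J, centering = VARIANTS[variant]
        except KeyError:
            raise ValueError(f"unknown variant {variant!r}; choose from {list(VARIANTS)}")
        return cls(fit_J=fit_J, centering=centering, **kwargs)


def compute_J_covariate(operator: RelationshipOperator) -> tuple[np.ndarray, np.ndarray]:
    """J over (genotyped, nongenotyped) individuals.

    Jg is −1 for every genotyped individual; Jn = Ang Agg^{-1} Jg, the
    pedigree regression of the genotyped −1s onto the nongenotyped; an
    entry of Jn equals −1 exactly when the individual's genotype is fully
    determined by genotyped ancestors.
    """
    Jg = -np.ones(operator.n_genotyped)
    Jn = operator.solve_nn_block(Jg[:, None])[:, 0]
    return Jg, Jn


def impute_marker_covariates(operator: RelationshipOperator, Mg: np.ndarray) -> np.ndarray:
    """Best-linear-prediction imputation Mhat_n = Ang Agg^{-1} Mg.

    The founder-mean terms of the conditional-expectation form cancel into
    the J covariate, so the uncentered product is the right quantity here.
    """
    return operator.solve_nn_block(np.asarray(Mg, dtype=float))


def apply_centering(
    Mg: np.ndarray,
    operator: RelationshipOperator,
    mode: str = "none",
    Mn_raw: np.ndarray | None = None,
    Jn: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Mg_used, Mn_used, centering_vector) for a centering mode.

    none           : covariates as allele counts.
    all_covariates : subtract column means taken over the stacked
                     imputed + observed matrix from every row.
    observed_only  : subtract column means of Mg from the observed rows,
                     then impute from the centered matrix; by linearity
                     Mhat_n(Mg - 1 v') = Mhat_n + Jn v'.
    """
    Mg = np.asarray(Mg, dtype=float)
    if Mn_raw is None:
        Mn_raw = impute_marker_covariates(operator, Mg)
    if mode == "none":
        return Mg, Mn_raw, np.zeros(Mg.shape[1])
    if mode == "all_covariates":
        total = Mg.shape[0] + Mn_raw.shape[0]
        v = (Mg.sum(axis=0) + Mn_raw.sum(axis=0)) / total
        return Mg - v, Mn_raw - v, v
    if mode == "observed_only":
        v = Mg.mean(axis=0)
        if Jn is None:
            _, Jn = compute_J_covariate(operator)
        return Mg - v, Mn_raw + np.outer(Jn, v), v
    raise ValueError(f"unknown centering mode {mode!r}")


@dataclass
class DesignSystem:
    """Assembled design for one (dataset, panel, centering) combination.

    Rows of ``M`` and entries of ``J`` are in pedigree order; ``eps_index``
    maps a pedigree position to its imputation-residual equation (−1 for
    genotyped individuals, which have none).
    """

    y: np.ndarray
    train_idx: np.ndarray  # pedigree positions with phenotypes
    J: np.ndarray  # (N,)
    M: np.ndarray  # (N, m) covariates after centering
    geno_mask: np.ndarray  # (N,) bool
    eps_index: np.ndarray  # (N,) int, -1 for genotyped
    A_inv_nn: sparse.csc_matrix
    sigma2_g: float
    sigma2_e: float
    sigma2_alpha: float
    centering_vector: np.ndarray
    panel: str
    operator: RelationshipOperator = field(repr=False)

    @property
    def n_markers(self) -> int:
        return self.M.shape[1]

    @property
    def n_eps(self) -> int:
        return self.A_inv_nn.shape[0]


def marker_prior_variance(Mg_raw: np.ndarray, sigma2_g: float, rule: str) -> float:
    """Per-marker prior variance partitioning sigma2_g across the panel."""
    m = Mg_raw.shape[1]
    if rule == "per_marker":
        return sigma2_g / m
    p = Mg_raw.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all panel loci fixed; cannot set marker prior variance")
    return sigma2_g / denom


def build_design(
    dataset: StudyDataset,
    spec: ModelSpec,
    panel: str = "qtl_plus_markers",
    operator: RelationshipOperator | None = None,
    Mn_raw: np.ndarray | None = None,
) -> DesignSystem:
    """Assemble the single-step design from a study dataset.

    ``operator`` and ``Mn_raw`` (the uncentered imputed covariates) may be
    passed in to reuse the cached nn-factorization and imputation solves
    across model variants fitted to the same data.
    """
    if operator is None:
        operator = RelationshipOperator(dataset.pedigree, dataset.genotyped_ids)
    Mg_raw = dataset.observed_genotypes(panel)
    if Mn_raw is None:
        Mn_raw = impute_marker_covariates(operator, Mg_raw)
    Jg, Jn = compute_J_covariate(operator)
    Mg_c, Mn_c, v = apply_centering(Mg_raw, operator, spec.centering, Mn_raw, Jn)

    N = dataset.pedigree.n
    geno = dataset.genotyped
    J = np.empty(N)
    J[geno] = Jg
    J[~geno] = Jn
    M = np.empty((N, Mg_raw.shape[1]))
    M[geno] = Mg_c
    M[~geno] = Mn_c
    eps_index = np.full(N, -1, dtype=np.int64)
    eps_index[~geno] = np.arange((~geno).sum())

    train_idx = np.flatnonzero(dataset.training_mask)
    sigma2_alpha = marker_prior_variance(
        Mg_raw, dataset.trait.sigma2_g, spec.marker_variance_rule
    )
    return DesignSystem(
        y=dataset.phenotype[train_idx],
        train_idx=train_idx,
        J=J,
        M=M,
        geno_mask=geno,
        eps_index=eps_index,
        A_inv_nn=operator.A_inv_nn,
        sigma2_g=dataset.trait.sigma2_g,
        sigma2_e=dataset.trait.sigma2_e,
        sigma2_alpha=sigma2_alpha,
        centering_vector=v,
        panel=panel,
        operator=operator,
    )


@dataclass
class ModelFit:
    """Point estimates and per-individual GEBVs from one analysis."""

    mu_hat: float
    mu_g_hat: float | None
    alpha_hat: np.ndarray
    epsilon_hat: np.ndarray
    gebv: np.ndarray
    method: str
    variant: str | None = None
    n_samples: int = 0
    mcse: dict = field(default_factory=dict)

    def components(self, design: DesignSystem) -> dict[str, np.ndarray]:
        """GEBV split into its mu_g-, marker- and epsilon-terms."""
        mu_g = self.mu_g_hat if self.mu_g_hat is not None else 0.0
        eps = np.zeros(design.J.size)
        has = design.eps_index >= 0
        eps[has] = self.epsilon_hat[design.eps_index[has]]
        return {
            "mu_g_term": design.J * mu_g,
            "marker_term": design.M @ self.alpha_hat,
            "epsilon_term": eps,
        }


def _fixed_marker_matrix(design: DesignSystem, fit_J: bool) -> np.ndarray:
    """Dense [1, (J), M] block over training rows."""
    rows = design.train_idx
    cols = [np.ones((rows.size, 1))]
    if fit_J:
        cols.append(design.J[rows, None])
    cols.append(design.M[rows])
    return np.hstack(cols)


def _check_J_identifiable(design: DesignSystem, fit_J: bool) -> None:
    if fit_J and design.train_idx.size and design.geno_mask[design.train_idx].all():
        raise SingularModelError(
            "every phenotyped individual is genotyped, so the J covariate is "
            "collinear with the intercept; drop mu_g (fit_J=False)"
        )


def solve_mme(design: DesignSystem, spec: ModelSpec) -> ModelFit:
    """Exact solution of the mixed-model equations (posterior mean).

    The (mu, mu_g, alpha) block is dense and small; the imputation-residual
    block is sparse with the structure of the nn-block of A^{-1} and is
    eliminated by a Schur complement after one sparse LU factorization.
    """
    _check_J_identifiable(design, spec.fit_J)
    m = design.n_markers
    p = 1 + int(spec.fit_J) + m
    lam_a = design.sigma2_e / design.sigma2_alpha
    lam_g = design.sigma2_e / design.sigma2_g

    if design.y.size == 0:
        return ModelFit(
            mu_hat=0.0,
            mu_g_hat=0.0 if spec.fit_J else None,
            alpha_hat=np.zeros(m),
            epsilon_hat=np.zeros(design.n_eps),
            gebv=np.zeros(design.J.size),
            method="mme",
        )

    X = _fixed_marker_matrix(design, spec.fit_J)
    penalty = np.zeros(p)
    penalty[1 + int(spec.fit_J):] = lam_a
    C11 = X.T @ X + np.diag(penalty)
    r1 = X.T @ design.y

    if design.n_eps == 0:  # everyone genotyped: plain ridge system
        try:
            b = dla.solve(C11, r1, assume_a="sym")
        except np.linalg.LinAlgError as e:
            raise SingularModelError(f"singular mixed-model system: {e}") from None
        fit = ModelFit(
            mu_hat=float(b[0]),
            mu_g_hat=float(b[1]) if spec.fit_J else None,
            alpha_hat=b[1 + int(spec.fit_J):],
            epsilon_hat=np.zeros(0),
            gebv=np.zeros(design.J.size),
            method="mme",
        )
        fit.gebv = compute_gebv(fit, design)
        return fit

    # imputation-residual equations: one per nongenotyped individual
    eps_of_train = design.eps_index[design.train_idx]
    has_eps = eps_of_train >= 0
    n_eps = design.n_eps
    d = np.zeros(n_eps)
    np.add.at(d, eps_of_train[has_eps], 1.0)
    C22 = (sparse.diags(d) + lam_g * design.A_inv_nn).tocsc()
    r2 = np.zeros(n_eps)
    np.add.at(r2, eps_of_train[has_eps], design.y[has_eps])
    C21 = np.zeros((n_eps, p))
    np.add.at(C21, eps_of_train[has_eps], X[has_eps])

    lu = splu(C22)
    Y = lu.solve(C21)  # C22^{-1} C21
    S = C11 - C21.T @ Y
    r = r1 - Y.T @ r2
    try:
        b = dla.solve(S, r, assume_a="sym")
    except np.linalg.LinAlgError as e:
        raise SingularModelError(f"singular mixed-model system: {e}") from None
    if not np.all(np.isfinite(b)):
        raise SingularModelError("singular mixed-model system (non-finite solution)")
    eps = lu.solve(r2) - Y @ b

    mu = float(b[0])
    mu_g = float(b[1]) if spec.fit_J else None
    alpha = b[1 + int(spec.fit_J):]
    fit = ModelFit(
        mu_hat=mu,
        mu_g_hat=mu_g,
        alpha_hat=alpha,
        epsilon_hat=eps,
        gebv=np.zeros(design.J.size),
        method="mme",
    )
    fit.gebv = compute_gebv(fit, design)
    return fit


def gibbs_bayesc0(design: DesignSystem, spec: ModelSpec) -> ModelFit:
    """Single-site Gibbs sampler for the same Gaussian model (pi = 0).

    Variances are fixed; each sweep updates mu, mu_g, every marker effect
    and every imputation residual from their scalar full conditionals,
    keeping the data-side residual vector adjusted so a sweep costs
    O(n m + nnz(A^nn)).  Posterior means over the retained samples are the
    point estimates; Monte Carlo standard errors come from batch means.
    """
    _check_J_identifiable(design, spec.fit_J)
    if spec.chain_length <= spec.burn_in:
        raise ValueError("chain_length must exceed burn_in")
    rng = substream(spec.seed, "gibbs")
    m = design.n_markers
    n_eps = design.n_eps
    lam = {"alpha": design.sigma2_e / design.sigma2_alpha}
    s2e = design.sigma2_e

    rows = design.train_idx
    X_one = np.ones(rows.size)
    Xj = design.J[rows]
    XM = design.M[rows]
    xx_one = rows.size
    xx_j = float(Xj @ Xj)
    xx_m = (XM**2).sum(axis=0)

    A_nn = design.A_inv_nn.tocsr()
    eps_of_train = design.eps_index[rows]
    has_eps = eps_of_train >= 0
    train_of_eps = np.full(n_eps, -1, dtype=np.int64)
    train_of_eps[eps_of_train[has_eps]] = np.flatnonzero(has_eps)
    d_eps = np.zeros(n_eps)
    np.add.at(d_eps, eps_of_train[has_eps], 1.0)

    mu = 0.0
    mu_g = 0.0
    alpha = np.zeros(m)
    eps = np.zeros(n_eps)
    e = design.y.copy()  # residual at current state (all effects start at 0)

    keep = spec.chain_length - spec.burn_in
    sums = {"mu": 0.0, "mu_g": 0.0}
    alpha_sum = np.zeros(m)
    eps_sum = np.zeros(n_eps)
    n_batches = min(20, keep)
    batch = np.zeros((n_batches, 2 + m))
    batch_size = keep / n_batches

    indptr, indices, data = A_nn.indptr, A_nn.indices, A_nn.data
    inv_s2g = 1.0 / design.sigma2_g

    for it in range(spec.chain_length):
        # intercept
        rhs = float(X_one @ e) + xx_one * mu
        new = rng.normal(rhs / xx_one, np.sqrt(s2e / xx_one))
        e += X_one * (mu - new)
        mu = new
        # mu_g
        if spec.fit_J:
            rhs = float(Xj @ e) + xx_j * mu_g
            prec = xx_j
            new = rng.normal(rhs / prec, np.sqrt(s2e / prec))
            e += Xj * (mu_g - new)
            mu_g = new
        # marker effects
        for j in range(m):
            xj = XM[:, j]
            rhs = float(xj @ e) + xx_m[j] * alpha[j]
            prec = xx_m[j] + lam["alpha"]
            new = rng.normal(rhs / prec, np.sqrt(s2e / prec))
            e += xj * (alpha[j] - new)
            alpha[j] = new
        # imputation residuals
        for i in range(n_eps):
            lo, hi = indptr[i], indptr[i + 1]
            cols = indices[lo:hi]
            vals = data[lo:hi]
            prior_prec = 0.0
            prior_rhs = 0.0
            for t in range(cols.size):
                c = cols[t]
                if c == i:
                    prior_prec = vals[t] * inv_s2g
                else:
                    prior_rhs -= vals[t] * inv_s2g * eps[c]
            ti = train_of_eps[i]
            if ti >= 0:
                data_rhs = (e[ti] + eps[i]) / s2e
                prec = d_eps[i] / s2e + prior_prec
            else:
                data_rhs = 0.0
                prec = prior_prec
            mean = (data_rhs + prior_rhs) / prec
            new = rng.normal(mean, np.sqrt(1.0 / prec))
            if ti >= 0:
                e[ti] += eps[i] - new
            eps[i] = new

        if it >= spec.burn_in:
            k = it - spec.burn_in
            sums["mu"] += mu
            sums["mu_g"] += mu_g
            alpha_sum += alpha
            eps_sum += eps
            b = min(int(k / batch_size), n_batches - 1)
            batch[b, 0] += mu
            batch[b, 1] += mu_g
            batch[b, 2:] += alpha

    counts = np.bincount(
        np.minimum((np.arange(keep) / batch_size).astype(int), n_batches - 1),
        minlength=n_batches,
    )
    bmeans = batch / counts[:, None]
    mcse_vec = bmeans.std(axis=0, ddof=1) / np.sqrt(n_batches)
    fit = ModelFit(
        mu_hat=sums["mu"] / keep,
        mu_g_hat=(sums["mu_g"] / keep) if spec.fit_J else None,
        alpha_hat=alpha_sum / keep,
        epsilon_hat=eps_sum / keep,
        gebv=np.zeros(design.J.size),
        method="gibbs",
        n_samples=keep,
        mcse={
            "mu": float(mcse_vec[0]),
            "mu_g": float(mcse_vec[1]),
            "alpha": mcse_vec[2:],
        },
    )
    fit.gebv = compute_gebv(fit, design)
    return fit


def compute_gebv(fit: ModelFit, design: DesignSystem) -> np.ndarray:
    """GEBV per pedigree member: J mu_g + M alpha (+ eps for nongenotyped)."""
    parts = fit.components(design)
    g = parts["marker_term"] + parts["epsilon_term"]
    if fit.mu_g_hat is not None:
        g = g + parts["mu_g_term"]
    return g


def fit_single_step(
    dataset: StudyDataset,
    variant: str = "J",
    panel: str = "qtl_plus_markers",
    method: str = "mme",
    operator: RelationshipOperator | None = None,
    Mn_raw: np.ndarray | None = None,
    **spec_kwargs,
) -> ModelFit:
    """Convenience wrapper: build the design for a named variant and fit."""
    spec = ModelSpec.from_variant(variant, **spec_kwargs)
    design = build_design(dataset, spec, panel=panel, operator=operator, Mn_raw=Mn_raw)
    if method == "mme":
        fit = solve_mme(design, spec)
    elif method == "gibbs":
        fit = gibbs_bayesc0(design, spec)
    else:
        raise ValueError("method must be 'mme' or 'gibbs'")
    fit.variant = variant
    return fit
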