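"""A compact single-trait BLUP engine.

Assembles and solves Henderson's mixed model equations for the model

    y = Xb + Zu + Wp + e,

with u the additive genetic effect (prior covariance A * sigma_g2 from the
pedigree numerator relationship matrix) and p optional iid random effects.
Solving is direct (sparse LU); the same factorisation yields the focal block
of the inverse coefficient matrix, i.e. the prediction error (co)variances
needed for exact confidence intervals, as well as per-animal reliabilities
and adjusted phenotypes.  Multi-trait data are handled by looping the
single-trait solver over traits (no cross-trait covariances).

The pedigree machinery provides the numerator relationship matrix A three
ways: inbreeding coefficients by the Meuwissen-Luo tracing algorithm, a
vectorised tabular-method dense A, and the sparse A-inverse from Henderson's
rules — the redundancy is deliberate, each route cross-checks the others in
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .errors import ConfigError, InvariantError, LRValidationError, ParseError
from .io import AdjustedPhenotypes, CovBlocks, FocalSet, SolutionTable, VarianceComponents

__all__ = [
    "Pedigree",
    "PhenotypeTable",
    "ModelSpec",
    "MmeSystem",
    "read_pedigree",
    "write_pedigree",
    "inbreeding",
    "relationship_matrix",
    "a_inverse",
    "vanraden_g",
    "read_phenotypes",
    "write_phenotypes",
    "solve_mme",
    "solutions_table",
    "pev_blocks",
    "g22_block",
    "covblocks_from_runs",
    "adjusted_phenotypes",
    "adjusted_phenotypes_from_solutions",
    "truncate_to_partial",
]


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Renumbered pedigree: animal ids 1..n, parents precede offspring, 0 = unknown."""

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=int)
        self.sire = np.asarray(self.sire, dtype=int)
        self.dam = np.asarray(self.dam, dtype=int)
        n = self.animal.size
        if not np.array_equal(self.animal, np.arange(1, n + 1)):
            raise InvariantError(
                "pedigree animals must be renumbered 1..n in ascending order"
            )
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par < 0) or np.any(par > n):
                raise InvariantError(f"{name} ids out of range")
            bad = np.nonzero(par >= self.animal)[0]
            if bad.size:
                i = bad[0]
                raise InvariantError(
                    f"animal {self.animal[i]} does not follow its {name} "
                    f"{par[i]}: pedigree is cyclic or not topologically sorted"
                )

    @property
    def n(self) -> int:
        return int(self.animal.size)


def read_pedigree(path: str | Path) -> Pedigree:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"pedigree file not found: {path}")
    try:
        arr = np.loadtxt(path, dtype=int, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed pedigree file: {exc}") from None
    if arr.shape[1] < 3:
        raise ParseError(f"{path}: pedigree needs 3 integer columns")
    return Pedigree(animal=arr[:, 0], sire=arr[:, 1], dam=arr[:, 2])


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, s, d in zip(ped.animal, ped.sire, ped.dam):
            fh.write(f"{a} {s} {d}\n")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo tracing algorithm.

    For each non-founder the diagonal A_ii = sum_j L_j^2 D_j is accumulated
    by tracing ancestor contributions L backwards; F_i = A_ii - 1.  D_j is
    the Mendelian-sampling variance coefficient of ancestor j.
    """
    n = ped.n
    s = ped.sire - 1  # -1 = unknown
    d = ped.dam - 1
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        fs = F[s[i]] if s[i] >= 0 else -1.0
        fd = F[d[i]] if d[i] >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s[i] < 0 or d[i] < 0:
            continue  # F stays 0
        L = np.zeros(i + 1)
        L[i] = 1.0
        a_ii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            a_ii += lj * lj * D[j]
            half = 0.5 * lj
            if s[j] >= 0:
                L[s[j]] += half
            if d[j] >= 0:
                L[d[j]] += half
        F[i] = a_ii - 1.0
    return F


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method."""
    n = ped.n
    s = ped.sire - 1
    d = ped.dam - 1
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0:
            A[i, :i] = 0.5 * A[si, :i]
            A[i, i] = 1.0
        elif di >= 0:
            A[i, :i] = 0.5 * A[di, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def a_inverse(
    ped: Pedigree, inbreeding_coeffs: np.ndarray | None = None
) -> sparse.csr_matrix:
    """Sparse A-inverse by Henderson's rules, accounting for inbreeding.

    ``inbreeding_coeffs`` may be supplied (e.g. from the tabular diagonal)
    to skip the Meuwissen-Luo pass.
    """
    n = ped.n
    F = inbreeding(ped) if inbreeding_coeffs is None else np.asarray(inbreeding_coeffs, float)
    if F.shape != (n,):
        raise LRValidationError("inbreeding coefficients do not match the pedigree")
    s = ped.sire - 1
    d = ped.dam - 1
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        parents = [p for p in (s[i], d[i]) if p >= 0]
        if len(parents) == 2:
            mend = 0.5 - 0.25 * (F[parents[0]] + F[parents[1]])
        elif len(parents) == 1:
            mend = 0.75 - 0.25 * F[parents[0]]
        else:
            mend = 1.0
        b = 1.0 / mend
        add(i, i, b)
        for p in parents:
            add(i, p, -0.5 * b)
            add(p, i, -0.5 * b)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * b)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def vanraden_g(
    markers: np.ndarray,
    freqs: np.ndarray | None = None,
    A22: np.ndarray | None = None,
    blend: float = 0.95,
) -> np.ndarray:
    """Genomic relationship matrix, first VanRaden method.

    G = Mc Mc' / (2 sum_j p_j (1-p_j)) with Mc the column-centred 0/1/2
    genotype matrix.  Monomorphic loci (frequency 0 or 1) are excluded with
    a warning.  When a pedigree block ``A22`` is supplied, the result is
    blended as ``blend * G + (1-blend) * A22`` so the matrix is invertible.
    """
    M = np.asarray(markers, dtype=float)
    if freqs is None:
        freqs = M.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0.0) & (freqs < 1.0)
    if not np.all(poly):
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic loci from G", stacklevel=2
        )
        M = M[:, poly]
        freqs = freqs[poly]
    if freqs.size == 0:
        raise LRValidationError("no polymorphic loci left to build G")
    Mc = M - 2.0 * freqs
    denom = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
    G = (Mc @ Mc.T) / denom
    if A22 is not None:
        if A22.shape != G.shape:
            raise LRValidationError("A22 block does not match the genotyped set")
        G = blend * G + (1.0 - blend) * np.asarray(A22, float)
    return G


# ---------------------------------------------------------------------------
# phenotypes and model
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Phenotype records with named columns.

    ``missing_flags`` names one 0/1 column per trait (1 = record missing for
    that trait); absent flags mean fully observed.  Missingness is never
    encoded by a magic value in the trait column.
    """

    data: pd.DataFrame
    id_col: str
    traits: list[str]
    missing_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        needed = [self.id_col, *self.traits, *self.missing_flags]
        for col in needed:
            if col not in self.data.columns:
                raise ConfigError(f"phenotype table lacks column {col!r}")
        if self.missing_flags and len(self.missing_flags) != len(self.traits):
            raise ConfigError("need one missing flag column per trait")

    @property
    def n_records(self) -> int:
        return len(self.data)

    def observed_mask(self, trait: int) -> np.ndarray:
        if not self.missing_flags:
            return np.ones(self.n_records, dtype=bool)
        return self.data[self.missing_flags[trait - 1]].to_numpy(dtype=int) == 0

    def check_in_pedigree(self, ped: Pedigree) -> None:
        ids = self.data[self.id_col].to_numpy(dtype=int)
        if ids.min() < 1 or ids.max() > ped.n:
            raise InvariantError("phenotyped animal absent from the pedigree")


def read_phenotypes(
    path: str | Path,
    columns: list[str],
    id_col: str,
    traits: list[str],
    missing_flags: list[str] | None = None,
) -> PhenotypeTable:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"phenotype file not found: {path}")
    frame = pd.read_csv(path, sep=r"\s+", header=None, names=columns, comment="#",
                        float_precision="round_trip")
    if frame.isna().any().any():
        raise ParseError(f"{path}: ragged or non-numeric phenotype rows")
    return PhenotypeTable(
        data=frame, id_col=id_col, traits=traits, missing_flags=missing_flags or []
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    cols = list(pheno.data.columns)
    with open(path, "w") as fh:
        for row in pheno.data.itertuples(index=False):
            out = []
            for col, v in zip(cols, row):
                if col in pheno.traits:
                    out.append("%.17g" % float(v))
                else:
                    out.append(str(int(v)))
            fh.write(" ".join(out) + "\n")


@dataclass
class ModelSpec:
    """Names the model's effects; numbering is fixed factors first, then the
    genetic effect, then extra iid random effects."""

    fixed: list[str]  # factor column names; 'mean' = overall mean
    genetic: str  # animal id column
    extra_random: list[tuple[str, str]] = field(default_factory=list)  # (name, column)

    @property
    def effect_names(self) -> list[str]:
        return [*self.fixed, self.genetic, *[n for n, _ in self.extra_random]]

    @property
    def n_effects(self) -> int:
        return len(self.fixed) + 1 + len(self.extra_random)

    @property
    def genetic_effect_number(self) -> int:
        return len(self.fixed) + 1

    def effect_number(self, name: str) -> int:
        try:
            return self.effect_names.index(name) + 1
        except ValueError:
            raise ConfigError(f"unknown effect {name!r}") from None


@dataclass
class MmeSystem:
    """A solved mixed-model-equation system for one trait."""

    C: sparse.csc_matrix
    rhs: np.ndarray
    sol: np.ndarray
    offsets: dict[int, tuple[int, int]]  # effect number -> (start, n_levels)
    model: ModelSpec
    trait: int
    sigma_g2: float
    sigma_e2: float
    inbreeding_coeffs: np.ndarray
    constrained: list[int] = field(default_factory=list)
    _lu: object | None = None

    @property
    def n_equations(self) -> int:
        return self.rhs.size

    def lu(self):
        if self._lu is None:
            self._lu = splu(self.C.tocsc())
        return self._lu

    def effect_solutions(self, effect: int) -> np.ndarray:
        start, n_lev = self.offsets[effect]
        return self.sol[start:start + n_lev]


def _design_levels(
    pheno: PhenotypeTable, model: ModelSpec, ped: Pedigree, mask: np.ndarray
) -> list[tuple[str, np.ndarray, int]]:
    """(effect name, 0-based level index per record, n_levels) per effect."""
    out = []
    data = pheno.data[mask]
    nrec = len(data)
    for name in model.fixed:
        if name == "mean":
            out.append(("mean", np.zeros(nrec, dtype=int), 1))
        else:
            lev = data[name].to_numpy(dtype=int)
            if lev.min() < 1:
                raise ConfigError(f"fixed factor {name!r} has non-positive levels")
            out.append((name, lev - 1, int(lev.max())))
    ids = data[model.genetic].to_numpy(dtype=int)
    if ids.min() < 1 or ids.max() > ped.n:
        raise InvariantError("phenotyped animal absent from the pedigree")
    out.append((model.genetic, ids - 1, ped.n))
    for name, col in model.extra_random:
        lev = data[col].to_numpy(dtype=int)
        if lev.min() < 1:
            raise ConfigError(f"random effect {name!r} has non-positive levels")
        out.append((name, lev - 1, int(lev.max())))
    return out


def solve_mme(
    pheno: PhenotypeTable,
    ped: Pedigree,
    vc: VarianceComponents,
    model: ModelSpec,
    trait: int = 1,
    ainv: sparse.spmatrix | None = None,
    inbreeding_coeffs: np.ndarray | None = None,
) -> MmeSystem:
    """Assemble and solve the MME for one trait (direct sparse LU).

    Fixed-effect confounding is handled deterministically: for every fixed
    factor after the first, the equation of its last level is zeroed (its
    solution is constrained to 0) and a warning lists the constrained
    levels.  The solution satisfies the constrained normal equations to a
    relative residual below 1e-10.
    """
    if not 1 <= trait <= vc.n_traits:
        raise ConfigError(f"trait {trait} out of range")
    mask = pheno.observed_mask(trait)
    if mask.sum() == 0:
        raise LRValidationError(f"no observed records for trait {trait}")
    trait_col = pheno.traits[trait - 1]
    y = pheno.data.loc[mask, trait_col].to_numpy(dtype=float)
    nrec = y.size

    blocks = _design_levels(pheno, model, ped, mask)
    offsets: dict[int, tuple[int, int]] = {}
    start = 0
    for e, (_, _, n_lev) in enumerate(blocks, start=1):
        offsets[e] = (start, n_lev)
        start += n_lev
    n_eq = start

    rows = np.concatenate([np.arange(nrec)] * len(blocks))
    cols = np.concatenate(
        [offsets[e][0] + lev for e, (_, lev, _) in enumerate(blocks, start=1)]
    )
    W = sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(nrec, n_eq)
    ).tocsr()

    rhs = W.T @ y

    sigma_g2 = vc.sigma_g2(trait)
    sigma_e2 = vc.sigma_e2(trait)
    if sigma_g2 <= 0 or sigma_e2 <= 0:
        raise ConfigError("genetic and residual variances must be positive")
    F = inbreeding(ped) if inbreeding_coeffs is None else np.asarray(inbreeding_coeffs, float)
    if ainv is None:
        ainv = a_inverse(ped, inbreeding_coeffs=F)
    g_no = model.genetic_effect_number
    g_start, g_n = offsets[g_no]
    lam = sigma_e2 / sigma_g2

    ainv_coo = ainv.tocoo()
    parts_r = [ainv_coo.row + g_start]
    parts_c = [ainv_coo.col + g_start]
    parts_v = [lam * ainv_coo.data]
    for k, (name, _col) in enumerate(model.extra_random):
        e_no = g_no + 1 + k
        var_k = vc.others.get(name)
        if var_k is None:
            raise ConfigError(f"no covariance matrix for random effect {name!r}")
        lam_k = sigma_e2 / float(var_k[trait - 1, trait - 1])
        s, m = offsets[e_no]
        diag = np.arange(s, s + m)
        parts_r.append(diag)
        parts_c.append(diag)
        parts_v.append(np.full(m, lam_k))
    base = (W.T @ W).tocoo()
    C = sparse.coo_matrix(
        (
            np.concatenate([base.data, *parts_v]),
            (
                np.concatenate([base.row, *parts_r]),
                np.concatenate([base.col, *parts_c]),
            ),
        ),
        shape=(n_eq, n_eq),
    ).tocsc()

    # identifiability: zero the last level of every fixed factor after the first
    constrained = []
    for e in range(2, len(model.fixed) + 1):
        s, m = offsets[e]
        constrained.append(s + m - 1)
    if constrained:
        warnings.warn(
            "confounded fixed factors: constrained the last level of "
            + ", ".join(model.fixed[1:]) + " to zero",
            stacklevel=2,
        )
        free = np.ones(n_eq, dtype=bool)
        free[constrained] = False
        coo = C.tocoo()
        keep = free[coo.row] & free[coo.col]
        rows_k = np.concatenate([coo.row[keep], np.asarray(constrained)])
        cols_k = np.concatenate([coo.col[keep], np.asarray(constrained)])
        vals_k = np.concatenate([coo.data[keep], np.ones(len(constrained))])
        C = sparse.coo_matrix((vals_k, (rows_k, cols_k)), shape=(n_eq, n_eq)).tocsc()
        rhs[constrained] = 0.0

    lu = splu(C)
    sol = lu.solve(rhs)
    resid = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-10:
        raise LRValidationError(
            f"MME solve did not converge (relative residual {resid:.2e})"
        )
    sys = MmeSystem(
        C=C, rhs=rhs, sol=sol, offsets=offsets, model=model, trait=trait,
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, inbreeding_coeffs=F,
        constrained=constrained,
    )
    sys._lu = lu
    return sys


def solutions_table(systems: "MmeSystem | list[MmeSystem]", dataset_tag: str = "") -> SolutionTable:
    """Solution records (trait, effect, level, value) for one or more solved traits."""
    if isinstance(systems, MmeSystem):
        systems = [systems]
    rows = []
    for sys_ in systems:
        for e, (start, n_lev) in sorted(sys_.offsets.items()):
            vals = sys_.sol[start:start + n_lev]
            for lev in range(n_lev):
                rows.append((sys_.trait, e, lev + 1, float(vals[lev])))
    frame = pd.DataFrame(rows, columns=["trait", "effect", "level", "value"])
    return SolutionTable(records=frame, dataset_tag=dataset_tag)


def pev_blocks(
    system: MmeSystem, focal: FocalSet
) -> tuple[np.ndarray, np.ndarray]:
    """Focal block of the inverse MME coefficient matrix, in variance units.

    Returns ``(C22, rel)``: the n x n prediction error (co)variance block
    PEV = sigma_e2 * (C^-1)_{focal,focal} for the genetic effect, and the
    per-animal reliabilities rel_i = 1 - PEV_ii / (sigma_g2 * (1 + F_i)).
    """
    g_start, g_n = system.offsets[system.model.genetic_effect_number]
    idx = focal.ids - 1
    if idx.min() < 0 or idx.max() >= g_n:
        raise LRValidationError(
            f"focal ids outside the genetic-effect equations (1..{g_n})"
        )
    eqs = g_start + idx
    rhs = np.zeros((system.n_equations, focal.n))
    rhs[eqs, np.arange(focal.n)] = 1.0
    cols = system.lu().solve(rhs)
    block = system.sigma_e2 * cols[eqs, :]
    block = 0.5 * (block + block.T)
    a_diag = 1.0 + system.inbreeding_coeffs[idx]
    rel = 1.0 - np.diag(block) / (system.sigma_g2 * a_diag)
    if rel.min() < -1e-6 or rel.max() > 1 + 1e-6:
        raise InvariantError("reliabilities escaped [0, 1]: inconsistent system")
    return block, np.clip(rel, 0.0, 1.0)


def g22_block(ped: Pedigree, focal: FocalSet, sigma_g2: float) -> np.ndarray:
    """Prior genetic covariance of the focal set, A22 * sigma_g2."""
    A = relationship_matrix(ped)
    idx = focal.ids - 1
    return sigma_g2 * A[np.ix_(idx, idx)]


def covblocks_from_runs(
    system_whole: MmeSystem,
    system_partial: MmeSystem,
    ped: Pedigree,
    focal: FocalSet,
) -> tuple[CovBlocks, np.ndarray, np.ndarray]:
    """CovBlocks (G22, Cp22, Cw22) plus whole/partial reliabilities."""
    cw, rel_w = pev_blocks(system_whole, focal)
    cp, rel_p = pev_blocks(system_partial, focal)
    g22 = g22_block(ped, focal, system_whole.sigma_g2)
    return (
        CovBlocks(G22=g22, Cp22=cp, Cw22=cw, trait=focal.trait),
        rel_w,
        rel_p,
    )


# ---------------------------------------------------------------------------
# adjusted phenotypes and data truncation
# ---------------------------------------------------------------------------

def adjusted_phenotypes_from_solutions(
    sol: SolutionTable,
    pheno: PhenotypeTable,
    model: ModelSpec,
    target_effect: int,
    trait: int = 1,
) -> AdjustedPhenotypes:
    """y* = y minus every estimated effect except the target effect.

    One record per observed animal for the trait; animals without a
    phenotype simply do not appear (predictivity may then use fewer
    individuals than the validation statistics)."""
    mask = pheno.observed_mask(trait)
    data = pheno.data[mask]
    y = data[pheno.traits[trait - 1]].to_numpy(dtype=float)
    ystar = y.copy()
    names = model.effect_names
    for e, name in enumerate(names, start=1):
        if e == target_effect:
            continue
        values = sol.values_for(trait, e)
        if name == "mean":
            lev = np.ones(len(data), dtype=int)
        elif e == model.genetic_effect_number:
            lev = data[model.genetic].to_numpy(dtype=int)
        else:
            col = name if name in data.columns else dict(model.extra_random)[name]
            lev = data[col].to_numpy(dtype=int)
        missing = sorted(set(lev) - set(values))
        if missing:
            raise LRValidationError(
                f"solutions for effect {e} ({name}) lack levels {missing[:10]}"
            )
        ystar -= np.array([values[v] for v in lev])
    frame = pd.DataFrame(
        {
            "level": data[pheno.id_col].to_numpy(dtype=int),
            "trait": trait,
            "ystar": ystar,
        }
    )
    return AdjustedPhenotypes(table=frame)


def adjusted_phenotypes(
    system: MmeSystem, pheno: PhenotypeTable, target_effect: int
) -> AdjustedPhenotypes:
    return adjusted_phenotypes_from_solutions(
        solutions_table(system), pheno, system.model, target_effect, system.trait
    )


def truncate_to_partial(
    pheno: PhenotypeTable,
    focal: "FocalSet | dict[int, FocalSet] | None" = None,
    generation_column: str | None = None,
    generation_cutoff: int | None = None,
) -> PhenotypeTable:
    """Partial dataset: focal records flagged missing, everything else intact.

    Either a focal set (per trait, or one for all traits) or a
    generation-cutoff rule (blank records with generation > cutoff) must be
    given.  The pedigree is untouched by design — only observations are
    removed."""
    data = pheno.data.copy()
    flags = list(pheno.missing_flags)
    if not flags:
        flags = [f"miss_{t}" for t in pheno.traits]
        for f in flags:
            data[f] = 0
    if generation_column is not None:
        if generation_cutoff is None:
            raise ConfigError("generation cutoff rule needs a cutoff value")
        hit = data[generation_column].to_numpy(dtype=int) > generation_cutoff
        for f in flags:
            data.loc[hit, f] = 1
    elif focal is not None:
        per_trait = (
            focal if isinstance(focal, dict)
            else {t: focal for t in range(1, len(pheno.traits) + 1)}
        )
        ids_all = data[pheno.id_col].to_numpy(dtype=int)
        for t, fs in per_trait.items():
            hit = np.isin(ids_all, fs.ids)
            data.loc[hit, flags[t - 1]] = 1
    else:
        raise ConfigError("truncation needs a focal set or a generation cutoff")
    out = PhenotypeTable(
        data=data, id_col=pheno.id_col, traits=list(pheno.traits), missing_flags=flags
    )
    for t in range(1, len(pheno.traits) + 1):
        if out.observed_mask(t).sum() == 0:
            raise LRValidationError(
                f"partial dataset is empty for trait {t}: nothing left to train on"
            )
    return out
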