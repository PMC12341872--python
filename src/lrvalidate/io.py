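"""Readers and writers for every file the validator touches.

All formats are plain whitespace-separated text, deliberately compatible in
spirit with the Blupf90 family of files:

* solution files — columns ``trait effect level solution`` (one optional
  header line), suffixed ``_whole`` / ``_partial``;
* focal ID lists — one renumbered integer ID per line;
* PEV stores — a documented text dialect replacing the undocumented binary
  ``ebv_pev`` layout: header ``n <n> <G22|Cp22|Cw22> <trait>`` followed by
  the full symmetric n x n matrix;
* reliability files — columns ``level rel``;
* adjusted-phenotype files — columns ``level trait ystar``;
* the parameter file — a minimal dialect carrying variance components, the
  model description for the bundled BLUP engine, and the OPTION vocabulary
  (``OPTION validation``, ``OPTION se``, ``OPTION predictive_ability``,
  ``OPTION nrepboot``, ``OPTION prefix``, ...).

IDs are assumed already renumbered to consecutive positive integers (the
renumbering step of the upstream pipeline); no string-ID mapping is done
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InvariantError, ParseError
from .stats import FocalBlock

__all__ = [
    "SolutionTable",
    "FocalSet",
    "VarianceComponents",
    "CovBlocks",
    "ReliabilityTable",
    "AdjustedPhenotypes",
    "RunConfig",
    "read_solutions",
    "write_solutions",
    "extract_focal",
    "read_focal_ids",
    "write_focal_ids",
    "read_pev_store",
    "write_pev_store",
    "read_reliabilities",
    "write_reliabilities",
    "read_adjusted_phenotypes",
    "write_adjusted_phenotypes",
    "heritability",
    "read_parameter_file",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# solution files
# ---------------------------------------------------------------------------

@dataclass
class SolutionTable:
    """Per-trait, per-effect, per-level solutions of a mixed-model run."""

    records: pd.DataFrame  # columns: trait, effect, level, value
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=["trait", "effect", "level"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise ParseError(
                f"duplicate solution record (trait={row.trait}, "
                f"effect={row.effect}, level={row.level})"
            )

    def values_for(self, trait: int, effect: int) -> dict[int, float]:
        sub = self.records[
            (self.records["trait"] == trait) & (self.records["effect"] == effect)
        ]
        return dict(zip(sub["level"].to_numpy(), sub["value"].to_numpy()))

    def __len__(self) -> int:
        return len(self.records)


def read_solutions(path: str | Path, dataset_tag: str = "") -> SolutionTable:
    """Parse a solution file (optional single header line is skipped)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"solution file not found: {path}")
    rows: list[tuple[int, int, int, float]] = []
    seen_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if not seen_data:
                # tolerate exactly one header line if it does not start
                # with an integer field
                try:
                    int(parts[0])
                except ValueError:
                    seen_data = True
                    continue
            seen_data = True
            try:
                rows.append(
                    (int(parts[0]), int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path}: malformed solution line {lineno}: {line.strip()!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path}: no records")
    frame = pd.DataFrame(rows, columns=["trait", "effect", "level", "value"])
    return SolutionTable(records=frame, dataset_tag=dataset_tag)


def write_solutions(table: SolutionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("trait effect level solution\n")
        for row in table.records.itertuples(index=False):
            fh.write(
                f"{row.trait} {row.effect} {row.level} {_FLOAT_FMT % row.value}\n"
            )


# ---------------------------------------------------------------------------
# focal sets
# ---------------------------------------------------------------------------

@dataclass
class FocalSet:
    """Ordered list of focal (testing) individual IDs for one trait.

    The input order defines the row order of every downstream vector and
    matrix.
    """

    trait: int
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        if self.ids.size == 0:
            raise ParseError("focal set is empty")
        if np.any(self.ids <= 0):
            raise ParseError("focal ids must be positive renumbered integers")
        if len(np.unique(self.ids)) != self.ids.size:
            raise ParseError("duplicate ids in focal set")

    @property
    def n(self) -> int:
        return int(self.ids.size)


def read_focal_ids(path: str | Path, trait: int = 1) -> FocalSet:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"focal ID file not found: {path}")
    ids = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                ids.append(int(s.split()[0]))
            except ValueError:
                raise ParseError(
                    f"{path}: malformed focal id on line {lineno}: {s!r}"
                ) from None
    return FocalSet(trait=trait, ids=np.array(ids, dtype=int))


def write_focal_ids(focal: FocalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in focal.ids:
            fh.write(f"{i}\n")


def extract_focal(
    sol_whole: SolutionTable,
    sol_partial: SolutionTable,
    effect: int,
    focal: FocalSet,
) -> FocalBlock:
    """Align u_w and u_p to the focal ID order for the requested effect.

    Every focal id must appear at the requested effect in both tables for
    the focal set's trait; missing ids are fatal (the prediction pairs must
    be complete).
    """
    w = sol_whole.values_for(focal.trait, effect)
    p = sol_partial.values_for(focal.trait, effect)
    missing_w = [int(i) for i in focal.ids if i not in w]
    missing_p = [int(i) for i in focal.ids if i not in p]
    if missing_w or missing_p:
        bits = []
        if missing_w:
            bits.append(f"missing from whole solutions: {missing_w[:20]}")
        if missing_p:
            bits.append(f"missing from partial solutions: {missing_p[:20]}")
        raise ParseError(
            f"focal ids absent at effect {effect}, trait {focal.trait}: "
            + "; ".join(bits)
        )
    u_w = np.array([w[i] for i in focal.ids], dtype=float)
    u_p = np.array([p[i] for i in focal.ids], dtype=float)
    return FocalBlock(trait=focal.trait, ids=focal.ids.copy(), u_w=u_w, u_p=u_p)


# ---------------------------------------------------------------------------
# variance components and heritability
# ---------------------------------------------------------------------------

def _check_symmetric_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.shape[0] != mat.shape[1]:
        raise ConfigError(f"{name} covariance matrix is not square")
    if not np.allclose(mat, mat.T, rtol=1e-8, atol=1e-12):
        raise ConfigError(f"{name} covariance matrix is not symmetric")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ConfigError(f"{name} covariance matrix is not positive semi-definite")
    return mat


@dataclass
class VarianceComponents:
    """Trait x trait covariance matrices of the model's random effects."""

    genetic: np.ndarray
    residual: np.ndarray
    others: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genetic = _check_symmetric_psd(self.genetic, "genetic")
        self.residual = _check_symmetric_psd(self.residual, "residual")
        self.others = {
            k: _check_symmetric_psd(v, k) for k, v in self.others.items()
        }
        if self.genetic.shape != self.residual.shape:
            raise ConfigError("genetic and residual matrices differ in size")
        for k, v in self.others.items():
            if v.shape != self.genetic.shape:
                raise ConfigError(f"covariance matrix {k!r} differs in size")

    @property
    def n_traits(self) -> int:
        return self.genetic.shape[0]

    def sigma_g2(self, trait: int) -> float:
        return float(self.genetic[trait - 1, trait - 1])

    def sigma_e2(self, trait: int) -> float:
        return float(self.residual[trait - 1, trait - 1])


def heritability(vc: VarianceComponents, trait: int, component: str = "genetic") -> float:
    """h2 of ``trait``: the component variance over the phenotypic variance.

    The phenotypic variance is the sum of the per-trait variances of every
    random component (genetic + others + residual).
    """
    if not 1 <= trait <= vc.n_traits:
        raise ConfigError(f"trait {trait} out of range (n_traits={vc.n_traits})")
    t = trait - 1
    total = vc.genetic[t, t] + vc.residual[t, t]
    total += sum(m[t, t] for m in vc.others.values())
    if total <= 0.0:
        raise ConfigError(f"zero phenotypic variance for trait {trait}")
    if component == "genetic":
        num = vc.genetic[t, t]
    elif component in vc.others:
        num = vc.others[component][t, t]
    else:
        raise ConfigError(f"unknown variance component {component!r}")
    return float(num / total)


# ---------------------------------------------------------------------------
# PEV / PEC stores
# ---------------------------------------------------------------------------

@dataclass
class CovBlocks:
    """The three n x n matrices needed for exact confidence intervals.

    ``G22`` is the prior genetic covariance of the focal set (trait-variance
    units); ``Cp22`` / ``Cw22`` are the prediction error (co)variance blocks
    from the partial / whole runs.  More data cannot increase PEV, hence
    ``diag(Cp22) >= diag(Cw22)``, and PEV never exceeds the prior variance,
    hence ``G22 - Cp22`` and ``G22 - Cw22`` are PSD.
    """

    G22: np.ndarray
    Cp22: np.ndarray
    Cw22: np.ndarray
    trait: int = 1

    def __post_init__(self) -> None:
        self.G22 = np.asarray(self.G22, dtype=float)
        self.Cp22 = np.asarray(self.Cp22, dtype=float)
        self.Cw22 = np.asarray(self.Cw22, dtype=float)
        n = self.G22.shape[0]
        for name, m in (("G22", self.G22), ("Cp22", self.Cp22), ("Cw22", self.Cw22)):
            if m.shape != (n, n):
                raise InvariantError(f"{name} is not {n}x{n}")
            _assert_symmetric(m, name)
        if np.any(np.diag(self.Cp22) < np.diag(self.Cw22) - 1e-8 * _scale(self.Cp22)):
            raise InvariantError(
                "diag(Cp22) < diag(Cw22): partial-run PEV smaller than whole-run "
                "PEV — the whole and partial PEV files are likely swapped"
            )
        for name, m in (("G22 - Cp22", self.G22 - self.Cp22),
                        ("G22 - Cw22", self.G22 - self.Cw22)):
            eig = np.linalg.eigvalsh(m)
            if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
                raise InvariantError(
                    f"{name} is not positive semi-definite "
                    "(PEV cannot exceed the prior variance)"
                )

    @property
    def n(self) -> int:
        return self.G22.shape[0]


def _scale(m: np.ndarray) -> float:
    return max(1.0, float(np.abs(m).max()))


def _assert_symmetric(m: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if np.abs(m - m.T).max() > tol * _scale(m):
        raise InvariantError(f"{name} is asymmetric beyond tolerance {tol:g}")


def _read_matrix_file(path: str | Path, expected_name: str, focal: FocalSet) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"PEV store file not found: {path}")
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != "n":
            raise ParseError(f"{path}: malformed PEV store header: {header}")
        n = int(header[1])
        name = header[2]
        trait = int(header[3])
        if name != expected_name:
            raise ParseError(
                f"{path}: expected matrix {expected_name!r}, found {name!r}"
            )
        if trait != focal.trait:
            raise ParseError(
                f"{path}: store is for trait {trait}, focal set is trait {focal.trait}"
            )
        if n != focal.n:
            raise ParseError(
                f"{path}: store holds {n} individuals, focal set has {focal.n}"
            )
        try:
            mat = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: malformed matrix body: {exc}") from None
    if mat.shape != (n, n):
        raise ParseError(f"{path}: matrix body is {mat.shape}, expected ({n}, {n})")
    _assert_symmetric(mat, str(path))
    return mat


def read_pev_store(
    path_whole: str | Path,
    path_partial: str | Path,
    path_G: str | Path,
    focal: FocalSet,
) -> CovBlocks:
    """Read the three matrix files of the PEV-store dialect.

    Row/column order is the focal order; symmetry and the CovBlocks
    invariants are enforced.
    """
    G22 = _read_matrix_file(path_G, "G22", focal)
    Cp22 = _read_matrix_file(path_partial, "Cp22", focal)
    Cw22 = _read_matrix_file(path_whole, "Cw22", focal)
    return CovBlocks(G22=G22, Cp22=Cp22, Cw22=Cw22, trait=focal.trait)


def write_pev_store(
    blocks: CovBlocks, prefix: str | Path, trait: int | None = None
) -> list[Path]:
    """Write ``<prefix>_G22``, ``<prefix>_Cp22``, ``<prefix>_Cw22``."""
    trait = blocks.trait if trait is None else trait
    written = []
    for name, mat in (("G22", blocks.G22), ("Cp22", blocks.Cp22), ("Cw22", blocks.Cw22)):
        path = Path(f"{prefix}_{name}")
        _write_matrix_file(path, mat, name, trait)
        written.append(path)
    return written


def _write_matrix_file(path: Path, mat: np.ndarray, name: str, trait: int) -> None:
    n = mat.shape[0]
    with open(path, "w") as fh:
        fh.write(f"n {n} {name} {trait}\n")
        for row in mat:
            fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")


def write_matrix_file(path: str | Path, mat: np.ndarray, name: str, trait: int) -> None:
    """Write a single store matrix (used by the BLUP engine per run)."""
    _assert_symmetric(np.asarray(mat, float), name)
    _write_matrix_file(Path(path), np.asarray(mat, float), name, trait)


# ---------------------------------------------------------------------------
# reliabilities and adjusted phenotypes
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityTable:
    """Per-individual reliabilities from the whole and partial runs."""

    table: pd.DataFrame  # columns: level, rel_whole, rel_partial

    def focal_subset(self, focal: FocalSet) -> "ReliabilityTable":
        indexed = self.table.set_index("level")
        missing = [int(i) for i in focal.ids if i not in indexed.index]
        if missing:
            raise ParseError(f"reliabilities missing for focal ids {missing[:20]}")
        sub = indexed.loc[focal.ids].reset_index()
        return ReliabilityTable(table=sub)

    @property
    def rel_whole(self) -> np.ndarray:
        return self.table["rel_whole"].to_numpy(dtype=float)

    @property
    def rel_partial(self) -> np.ndarray:
        return self.table["rel_partial"].to_numpy(dtype=float)


def _read_rel_file(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"reliability file not found: {path}")
    try:
        frame = pd.read_csv(
            path, sep=r"\s+", header=None, names=["level", "rel"], comment="#",
            float_precision="round_trip",
        )
        frame["level"] = frame["level"].astype(int)
        frame["rel"] = frame["rel"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: malformed reliability file: {exc}") from None
    if frame["rel"].min() < -1e-8 or frame["rel"].max() > 1 + 1e-8:
        import warnings

        warnings.warn(f"{path}: reliabilities outside [0, 1]", stacklevel=2)
    return frame


def read_reliabilities(path_whole: str | Path, path_partial: str | Path) -> ReliabilityTable:
    w = _read_rel_file(path_whole).rename(columns={"rel": "rel_whole"})
    p = _read_rel_file(path_partial).rename(columns={"rel": "rel_partial"})
    merged = w.merge(p, on="level", how="inner")
    if merged.empty:
        raise ParseError("whole and partial reliability files share no levels")
    return ReliabilityTable(table=merged)


def write_reliabilities(levels: np.ndarray, rel: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lev, r in zip(levels, rel):
            fh.write(f"{int(lev)} {_FLOAT_FMT % r}\n")


@dataclass
class AdjustedPhenotypes:
    """Adjusted phenotypes y*, keyed by renumbered ID and trait."""

    table: pd.DataFrame  # columns: level, trait, ystar

    def for_focal(self, focal: FocalSet) -> np.ndarray:
        sub = self.table[self.table["trait"] == focal.trait].set_index("level")
        missing = [int(i) for i in focal.ids if i not in sub.index]
        if missing:
            raise ParseError(
                f"adjusted phenotypes missing for focal ids {missing[:20]} "
                f"(trait {focal.trait})"
            )
        return sub.loc[focal.ids, "ystar"].to_numpy(dtype=float)


def read_adjusted_phenotypes(path: str | Path) -> AdjustedPhenotypes:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"adjusted-phenotype file not found: {path}")
    try:
        frame = pd.read_csv(
            path, sep=r"\s+", header=None, names=["level", "trait", "ystar"],
            comment="#", float_precision="round_trip",
        )
        frame["level"] = frame["level"].astype(int)
        frame["trait"] = frame["trait"].astype(int)
        frame["ystar"] = frame["ystar"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: malformed adjusted-phenotype file: {exc}") from None
    return AdjustedPhenotypes(table=frame)


def write_adjusted_phenotypes(adj: AdjustedPhenotypes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in adj.table.itertuples(index=False):
            fh.write(f"{int(row.level)} {int(row.trait)} {_FLOAT_FMT % row.ystar}\n")


# ---------------------------------------------------------------------------
# parameter file
# ---------------------------------------------------------------------------

_KNOWN_OPTIONS = {
    "validation",
    "se",
    "predictive_ability",
    "nrepboot",
    "prefix",
    "pev_prefix",
    "rel_prefix",
    "yhat_file",
    "focal_variance",
    "sigma_gi",
    "alpha",
    "seed",
    "store_pev_pec",
    "include_effects",
    "solfile",
}


@dataclass
class RunConfig:
    """Everything a run needs, parsed from the parameter-file dialect."""

    vc: VarianceComponents | None = None
    # model / data description (needed by blup, predict, simulate-free runs)
    data_file: str | None = None
    data_file_partial: str | None = None
    ped_file: str | None = None
    columns: list[str] = field(default_factory=list)
    id_col: str | None = None
    fixed: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)
    missing_flags: list[str] = field(default_factory=list)
    # options
    validation_effect: int | None = None
    focal_files: list[str] = field(default_factory=list)
    se_mode: str | None = None
    predictive_ability: bool = False
    n_boot: int = 10_000
    prefix: str = "solutions"
    pev_prefix: str = "pev"
    rel_prefix: str = "acc"
    yhat_file: str = "yhat_residual"
    focal_variance: float | None = None
    sigma_gi_mode: str = "from_parfile"
    alpha: float = 0.05
    seed: int = 0
    store_pev_pec: bool = False
    include_effects: int | None = None
    solfile: str | None = None
    genetic_column: str | None = None
    random_effects: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        if self.vc is None:
            raise ConfigError("parameter file carries no variance components")
        return self.vc.n_traits

    def focal_file_for(self, trait: int) -> str:
        """One focal file is replicated across traits; k files require k == n_traits."""
        if not self.focal_files:
            raise ConfigError("OPTION validation with focal ID files is required")
        if len(self.focal_files) == 1:
            return self.focal_files[0]
        if len(self.focal_files) != self.n_traits:
            raise ConfigError(
                f"{len(self.focal_files)} focal files given for "
                f"{self.n_traits} traits (need 1 or {self.n_traits})"
            )
        return self.focal_files[trait - 1]


def _parse_matrix(lines: list[str], start: int, n: int, path: Path, key: str) -> tuple[np.ndarray, int]:
    rows = []
    i = start
    while len(rows) < n:
        if i >= len(lines):
            raise ParseError(f"{path}: {key}: expected {n} matrix rows")
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        try:
            row = [float(x) for x in parts]
        except ValueError:
            raise ParseError(f"{path}: {key}: malformed matrix row {i}: {lines[i-1]!r}") from None
        if len(row) != n:
            raise ParseError(f"{path}: {key}: matrix row has {len(row)} entries, expected {n}")
        rows.append(row)
    return np.array(rows), i


def read_parameter_file(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"parameter file not found: {path}")
    lines = path.read_text().splitlines()
    cfg = RunConfig()
    n_traits: int | None = None
    genetic = residual = None
    others: dict[str, np.ndarray] = {}
    random_effects: list[tuple[str, str]] = []  # (name, column)
    genetic_column: str | None = None

    i = 0
    while i < len(lines):
        raw = lines[i]
        i += 1
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0].upper()
        if key == "N_TRAITS":
            n_traits = int(parts[1])
        elif key == "DATAFILE":
            cfg.data_file = parts[1]
        elif key == "DATAFILE_PARTIAL":
            cfg.data_file_partial = parts[1]
        elif key == "PEDFILE":
            cfg.ped_file = parts[1]
        elif key == "COLUMNS":
            cfg.columns = parts[1:]
        elif key == "ID":
            cfg.id_col = parts[1]
        elif key == "FIXED":
            cfg.fixed = parts[1:]
        elif key == "TRAITS":
            cfg.traits = parts[1:]
        elif key == "MISSING_FLAGS":
            cfg.missing_flags = parts[1:]
        elif key == "GENETIC_EFFECT":
            genetic_column = parts[1]
        elif key == "RANDOM_EFFECT":
            if len(parts) != 3:
                raise ParseError(f"{path}: RANDOM_EFFECT needs a name and a column")
            random_effects.append((parts[1], parts[2]))
        elif key in ("GENETIC_COVARIANCE", "RESIDUAL_COVARIANCE", "RANDOM_COVARIANCE"):
            if n_traits is None:
                raise ParseError(f"{path}: N_TRAITS must precede covariance blocks")
            name = parts[1] if key == "RANDOM_COVARIANCE" else None
            mat, i = _parse_matrix(lines, i, n_traits, path, key)
            if key == "GENETIC_COVARIANCE":
                genetic = mat
            elif key == "RESIDUAL_COVARIANCE":
                residual = mat
            else:
                others[name] = mat
        elif key == "OPTION":
            _apply_option(cfg, parts[1:], path)
        else:
            raise ParseError(f"{path}: unknown keyword {parts[0]!r}")

    if genetic is not None or residual is not None:
        if genetic is None or residual is None:
            raise ConfigError(
                f"{path}: both GENETIC_COVARIANCE and RESIDUAL_COVARIANCE are required"
            )
        cfg.vc = VarianceComponents(genetic=genetic, residual=residual, others=others)
    cfg.genetic_column = genetic_column
    cfg.random_effects = random_effects
    return cfg


def _apply_option(cfg: RunConfig, args: list[str], path: Path) -> None:
    if not args:
        raise ConfigError(f"{path}: empty OPTION line")
    name = args[0]
    if name not in _KNOWN_OPTIONS:
        raise ConfigError(
            f"{path}: unknown OPTION {name!r} (unknown options are fatal, not ignored)"
        )
    try:
        if name == "validation":
            cfg.validation_effect = int(args[1])
            cfg.focal_files = args[2:]
            if not cfg.focal_files:
                raise ConfigError(
                    f"{path}: OPTION validation needs at least one focal ID file"
                )
        elif name == "se":
            mode = args[1]
            if mode not in ("exact", "approx", "boot"):
                raise ConfigError(f"{path}: OPTION se mode must be exact|approx|boot")
            cfg.se_mode = mode
        elif name == "predictive_ability":
            cfg.predictive_ability = True
        elif name == "nrepboot":
            cfg.n_boot = int(args[1])
            if cfg.n_boot < 1:
                raise ConfigError(f"{path}: nrepboot must be positive")
        elif name == "prefix":
            cfg.prefix = args[1]
        elif name == "pev_prefix":
            cfg.pev_prefix = args[1]
        elif name == "rel_prefix":
            cfg.rel_prefix = args[1]
        elif name == "yhat_file":
            cfg.yhat_file = args[1]
        elif name == "focal_variance":
            cfg.focal_variance = float(args[1])
            cfg.sigma_gi_mode = "user"
        elif name == "sigma_gi":
            mode = args[1]
            if mode not in ("parfile", "g22", "user"):
                raise ConfigError(f"{path}: OPTION sigma_gi must be parfile|g22|user")
            cfg.sigma_gi_mode = {"parfile": "from_parfile", "g22": "from_G22", "user": "user"}[mode]
        elif name == "alpha":
            cfg.alpha = float(args[1])
            if not 0.0 < cfg.alpha < 1.0:
                raise ConfigError(f"{path}: alpha must lie in (0, 1)")
        elif name == "seed":
            cfg.seed = int(args[1])
        elif name == "store_pev_pec":
            cfg.store_pev_pec = True
        elif name == "include_effects":
            cfg.include_effects = int(args[1])
        elif name == "solfile":
            cfg.solfile = args[1]
    except IndexError:
        raise ConfigError(f"{path}: OPTION {name} is missing its argument") from None
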