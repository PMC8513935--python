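"""Calibration machinery: rmsd objective and parameter fitting.

The model's empirical parameters (solvent constants, secondary-site
SSIP values) are calibrated by minimising the root-mean-square
deviation between calculated and experimental solvent-solvent transfer
free energies.  The optimiser is derivative-free: cyclic coordinate
descent with a shrinking step, followed by a Nelder-Mead polish.  SSIP
counts per atom are structural integers and are never free parameters.

A synthetic partition-data generator is provided for parameter-recovery
testing: it emulates a table of solvent-solvent transfer measurements
(the field's data are water-to-organic transfer free energies of small
monofunctional solutes, with experimental scatter of roughly 1-2 kJ/mol)
by adding Gaussian noise to the model's own predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .assignment import assign_atom_codes, build_ssip_profile, parse_structure
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .errors import ChemistryError, NumericError
from .parameters import DEFAULT_REGISTRY, Registry
from .solvation import transfer_free_energy

DATASET_COLUMNS = ("solute", "smiles", "solvent_from", "solvent_to", "dG_kJmol", "source")


def rmsd(calculated: Sequence[float], experimental: Sequence[float]) -> float:
    """Root-mean-square deviation between two equal-length vectors (kJ/mol)."""
    calc = np.asarray(calculated, dtype=float)
    expt = np.asarray(experimental, dtype=float)
    if calc.shape != expt.shape or calc.size == 0:
        raise ValueError(
            f"need equal non-empty vectors, got lengths {calc.size} and {expt.size}"
        )
    return float(np.sqrt(np.mean((calc - expt) ** 2)))


@dataclass
class PartitionDataset:
    """Experimental (or synthetic) solvent-solvent transfer free energies."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        key = self.records[["solute", "solvent_from", "solvent_to"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate (solute, solvent pair) keys: {dupes[:5]}")
        if not np.isfinite(self.records["dG_kJmol"]).all():
            raise ValueError("non-finite dG_kJmol values in dataset")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PartitionDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, columns=list(DATASET_COLUMNS))


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` maps registry parameter paths (see
    :meth:`ssipsolv.parameters.Registry.get_param`) to (lower, upper)
    bounds.  Frozen parameters are simply everything not listed.
    """

    free: Mapping[str, tuple[float, float]]
    tol: float = 1e-4  # kJ/mol, convergence tolerance on the rmsd
    max_sweeps: int = 500
    seed: int = 0
    initial_step: float = 0.25  # kJ/mol-scale first coordinate step

    def __post_init__(self) -> None:
        for path, (lo, hi) in self.free.items():
            if not lo < hi:
                raise ValueError(f"bad bounds for {path!r}: ({lo}, {hi})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FitSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        free = {k: tuple(v) for k, v in raw.get("free", {}).items()}
        kwargs = {k: raw[k] for k in ("tol", "max_sweeps", "seed", "initial_step") if k in raw}
        return cls(free=free, **kwargs)


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    params: dict[str, float]  # optimised values by parameter path
    rmsd: float  # final rmsd, kJ/mol
    initial_rmsd: float
    residuals: np.ndarray  # calculated - experimental, kJ/mol
    trace: list[float]  # best rmsd after each sweep (non-increasing)
    n_sweeps: int
    frozen: tuple[str, ...] = ()  # parameters frozen for zero sensitivity
    registry: Registry | None = None  # registry with fitted values applied


class _Predictor:
    """Cached structure analysis; profiles rebuilt per candidate registry."""

    def __init__(self, dataset: PartitionDataset, constants: ModelConstants) -> None:
        self.constants = constants
        self.rows = dataset.records
        self._structures: dict[str, tuple] = {}
        for smiles in self.rows["smiles"].unique():
            try:
                mol = parse_structure(smiles)
                self._structures[smiles] = (mol, assign_atom_codes(mol))
            except ChemistryError as err:
                raise ChemistryError(f"solute {smiles!r} is not assignable: {err}") from err

    def __call__(self, registry: Registry) -> np.ndarray:
        profiles = {
            smiles: build_ssip_profile(codes, mol, registry)
            for smiles, (mol, codes) in self._structures.items()
        }
        out = np.empty(len(self.rows))
        for i, row in enumerate(self.rows.itertuples(index=False)):
            out[i] = transfer_free_energy(
                profiles[row.smiles],
                row.solvent_from,
                row.solvent_to,
                constants=self.constants,
                registry=registry,
            ).dg
        return out


class ParameterFit:
    """RMSD minimiser over selected registry parameters.

    Follows the fit/result idiom: construct with a spec, call
    :meth:`fit` with a dataset, read the fitted state from the returned
    :class:`FitResult` (the source registry is never mutated).
    """

    def __init__(
        self,
        spec: FitSpec,
        registry: Registry | None = None,
        constants: ModelConstants = DEFAULT_CONSTANTS,
    ) -> None:
        self.spec = spec
        self.registry = registry or DEFAULT_REGISTRY
        self.constants = constants

    def fit(self, dataset: PartitionDataset) -> FitResult:
        predict = _Predictor(dataset, self.constants)
        expt = dataset.records["dG_kJmol"].to_numpy(dtype=float)

        paths = sorted(self.spec.free)  # deterministic order
        bounds = [self.spec.free[p] for p in paths]
        x0 = np.array([self.registry.get_param(p) for p in paths])

        def objective(x: np.ndarray) -> float:
            reg = self.registry.with_params(dict(zip(paths, x)))
            value = rmsd(predict(reg), expt)
            if not math.isfinite(value):
                raise NumericError(
                    f"non-finite rmsd at parameter vector {dict(zip(paths, x))}"
                )
            return value

        initial = rmsd(predict(self.registry), expt)
        if not paths:
            return FitResult(
                params={},
                rmsd=initial,
                initial_rmsd=initial,
                residuals=predict(self.registry) - expt,
                trace=[initial],
                n_sweeps=0,
                registry=self.registry,
            )

        # identifiability guardrail: freeze parameters the data cannot see
        frozen: list[str] = []
        h = 1e-3
        for i, p in enumerate(paths):
            xp = x0.copy()
            xp[i] += h * max(1.0, abs(xp[i]))
            if abs(objective(np.clip(xp, *zip(*bounds))) - initial) < 1e-12:
                frozen.append(p)
        if frozen:
            warnings.warn(
                f"parameters with zero sensitivity frozen: {', '.join(frozen)}",
                stacklevel=2,
            )
            paths = [p for p in paths if p not in frozen]
            bounds = [self.spec.free[p] for p in paths]
            x0 = np.array([self.registry.get_param(p) for p in paths])
            if not paths:
                return FitResult(
                    params={},
                    rmsd=initial,
                    initial_rmsd=initial,
                    residuals=predict(self.registry) - expt,
                    trace=[initial],
                    n_sweeps=0,
                    frozen=tuple(frozen),
                    registry=self.registry,
                )

        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        # stage 1: cyclic coordinate descent with shrinking step
        x = x0.copy()
        best = objective(x)
        trace = [best]
        steps = np.full(len(paths), self.spec.initial_step)
        sweeps = 0
        for sweeps in range(1, self.spec.max_sweeps + 1):
            improved = False
            for i in range(len(paths)):
                for sign in (+1.0, -1.0):
                    trial = x.copy()
                    trial[i] = np.clip(trial[i] + sign * steps[i], lo[i], hi[i])
                    if trial[i] == x[i]:
                        continue
                    val = objective(trial)
                    if val < best - 1e-15:
                        x, best, improved = trial, val, True
                        break
            if not improved:
                steps *= 0.5
            trace.append(best)
            if steps.max() < self.spec.tol / 10 or (
                len(trace) > 2 and trace[-3] - best < self.spec.tol and not improved
            ):
                break

        # stage 2: simplex polish
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": max(self.spec.tol * 1e-4, 1e-9),
                     "fatol": max(self.spec.tol * 1e-8, 1e-13),
                     "maxiter": 400 * len(paths)},
        )
        if res.fun <= best:
            x, best = np.clip(res.x, lo, hi), float(res.fun)
        trace.append(best)

        fitted = dict(zip(paths, map(float, x)))
        reg = self.registry.with_params(fitted)
        return FitResult(
            params=fitted,
            rmsd=best,
            initial_rmsd=initial,
            residuals=predict(reg) - expt,
            trace=trace,
            n_sweeps=sweeps,
            frozen=tuple(frozen),
            registry=reg,
        )


def fit_parameters(
    dataset: PartitionDataset,
    spec: FitSpec,
    registry: Registry | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> FitResult:
    """Functional wrapper over :class:`ParameterFit`."""
    return ParameterFit(spec, registry, constants).fit(dataset)


def simulate_partition_dataset(
    solutes: Mapping[str, str] | Sequence[str],
    solvents: Sequence[str],
    noise_sd: float = 0.0,
    seed: int = 0,
    solvent_from: str = "water",
    registry: Registry | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> PartitionDataset:
    """Synthetic transfer dataset: model prediction plus Gaussian noise.

    ``solutes`` is a mapping of id -> SMILES (or a plain sequence of
    SMILES); records are generated for transfer from ``solvent_from``
    into every solvent in ``solvents``.  Reproducible for a given seed.
    """
    registry = registry or DEFAULT_REGISTRY
    if not isinstance(solutes, Mapping):
        solutes = {s: s for s in solutes}
    rng = np.random.default_rng(seed)
    rows = []
    for sid, smiles in solutes.items():
        try:
            mol = parse_structure(smiles)
            profile = build_ssip_profile(
                assign_atom_codes(mol), mol, registry, molecule_id=sid
            )
        except ChemistryError as err:
            raise ChemistryError(f"solute {smiles!r} is not assignable: {err}") from err
        for solvent in solvents:
            if registry.resolve_solvent(solvent) == registry.resolve_solvent(solvent_from):
                continue
            res = transfer_free_energy(
                profile, solvent_from, solvent, constants=constants, registry=registry
            )
            rows.append(
                {
                    "solute": sid,
                    "smiles": smiles,
                    "solvent_from": res.solvent_from,
                    "solvent_to": res.solvent_to,
                    "dG_kJmol": res.dg,
                    "source": "synthetic",
                }
            )
    frame = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    if noise_sd > 0:
        frame["dG_kJmol"] += rng.normal(0.0, noise_sd, size=len(frame))
    return PartitionDataset(frame)
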