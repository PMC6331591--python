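"""Host-variability cohort: factorial grid, batch simulation, dataset I/O."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as _p
from .metrics import pd_metrics, percent_protected, pk_metrics
from .params import Discretization, ParamError, TransportParams
from .transport import simulate, volume_average

__all__ = [
    "VariationGrid",
    "CohortDataset",
    "CohortError",
    "build_variation_grid",
    "run_cohort",
    "run_cases",
    "sample_cases",
    "split_dataset",
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "COHORT_COLUMNS",
]

FEATURE_COLUMNS = ["blood_Cmax", "blood_tmax", "blood_AUC", "blood_C24"]
TARGET_COLUMNS = ["stroma_Cmax", "stroma_tmax", "stroma_AUC", "stroma_C24",
                  "t_lag", "PPmax"]
PARAM_COLUMNS = ["he_um", "kD_per_hr", "kB_per_hr"]
COHORT_COLUMNS = ["case_id"] + PARAM_COLUMNS + FEATURE_COLUMNS + TARGET_COLUMNS


class CohortError(RuntimeError):
    """Raised when one or more cohort cases fail; carries partial results."""

    def __init__(self, message: str, failures: list, partial: "CohortDataset"):
        super().__init__(message)
        self.failures = failures
        self.partial = partial


@dataclass(frozen=True)
class VariationGrid:
    """Full-factorial levels of the three varied host parameters."""

    he_levels: tuple        # um
    kD_levels: tuple        # 1/hr
    kB_levels: tuple        # 1/hr

    def __post_init__(self) -> None:
        for name, levels in (("he_levels", self.he_levels),
                             ("kD_levels", self.kD_levels),
                             ("kB_levels", self.kB_levels)):
            vals = tuple(float(v) for v in levels)
            object.__setattr__(self, name, vals)
            if len(vals) == 0:
                raise ParamError(f"{name}: must be non-empty")
            if any(v <= 0 or not np.isfinite(v) for v in vals):
                raise ParamError(f"{name}: all levels must be positive")
            if len(set(vals)) != len(vals):
                raise ParamError(f"{name}: duplicate levels {vals}")

    @property
    def n_cases(self) -> int:
        return len(self.he_levels) * len(self.kD_levels) * len(self.kB_levels)

    def cases(self) -> list[tuple[float, float, float]]:
        """Deterministic enumeration: he outer, kD middle, kB inner."""
        return [(he, kD, kB)
                for he in self.he_levels
                for kD in self.kD_levels
                for kB in self.kB_levels]


@dataclass
class CohortDataset:
    """Per-case parameter triples with blood/stromal summary metrics."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in sorted(self.provenance.items()):
                fh.write(f"# {key}={value}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortDataset":
        provenance = {}
        with open(path, encoding="utf-8") as fh:
            while True:
                pos = fh.tell()
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    provenance[key.strip()] = value.strip()
            table = pd.read_csv(fh)
        missing = [c for c in COHORT_COLUMNS if c not in table.columns]
        if missing:
            raise ParamError(
                f"dataset is missing required column(s): {', '.join(missing)}")
        return cls(table=table, provenance=provenance)


def build_variation_grid(config: dict | None = None) -> VariationGrid:
    """Default canonical grid: 5 levels per parameter, 125 cases.

    ``config`` may override ``he_levels`` / ``kD_levels`` / ``kB_levels``
    (e.g. the 7-level epithelial-thickness list in
    :data:`mucosim.params.HE_LEVELS_7_UM`).
    """
    config = dict(config or {})
    he = config.pop("he_levels", _p.HE_LEVELS_UM)
    kD = config.pop("kD_levels", _p.KD_LEVELS_PER_HR)
    kB = config.pop("kB_levels", _p.KB_LEVELS_PER_HR)
    if config:
        raise ParamError(f"unknown grid config key(s): "
                         f"{', '.join(sorted(config))}")
    return VariationGrid(he_levels=tuple(he), kD_levels=tuple(kD),
                         kB_levels=tuple(kB))


def _case_row(case_id: int, he: float, kD: float, kB: float,
              base: TransportParams, disc: Discretization) -> dict:
    p = base.replace(he=he, kD=kD, kB=kB)
    res = simulate(p, disc)
    t_end = disc.t_end
    blood = pk_metrics(volume_average(res, "blood"), res.times, t_end)
    stroma = pk_metrics(volume_average(res, "stroma"), res.times, t_end)
    pp = percent_protected(res.dp_stroma, p.EC50)
    pd_ = pd_metrics(pp, res.times)
    return {
        "case_id": case_id,
        "he_um": he, "kD_per_hr": kD, "kB_per_hr": kB,
        "blood_Cmax": blood.Cmax, "blood_tmax": blood.tmax,
        "blood_AUC": blood.AUC, "blood_C24": blood.C24,
        "stroma_Cmax": stroma.Cmax, "stroma_tmax": stroma.tmax,
        "stroma_AUC": stroma.AUC, "stroma_C24": stroma.C24,
        "t_lag": pd_.t_lag, "PPmax": pd_.PPmax,
    }


def run_cases(triples, base: TransportParams | None = None,
              disc: Discretization | None = None,
              provenance: dict | None = None,
              progress=None) -> CohortDataset:
    """Simulate an explicit list of (he, kD, kB) triples.

    Failed cases are isolated: the remaining cases still run and a
    :class:`CohortError` carrying the partial dataset and the failing
    triples is raised at the end.
    """
    base = base if base is not None else _p.default_params()
    disc = disc if disc is not None else _p.default_discretization()
    rows, failures = [], []
    for case_id, (he, kD, kB) in enumerate(triples):
        try:
            rows.append(_case_row(case_id, he, kD, kB, base, disc))
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            failures.append(((he, kD, kB), exc))
        if progress is not None:
            progress(case_id, (he, kD, kB))
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    dataset = CohortDataset(table=table, provenance=dict(provenance or {}))
    if failures:
        msg = ", ".join(f"(he={he}, kD={kD}, kB={kB}): {exc}"
                        for (he, kD, kB), exc in failures)
        raise CohortError(
            f"{len(failures)} of {len(list(triples))} cohort case(s) "
            f"failed: {msg}", failures, dataset)
    return dataset


def run_cohort(grid: VariationGrid, base: TransportParams | None = None,
               disc: Discretization | None = None,
               progress=None) -> CohortDataset:
    """Simulate every grid case and tabulate its summary metrics.

    One simulation plus metric evaluation per case, in the grid's
    deterministic enumeration order (he outer, kD middle, kB inner).
    """
    base = base if base is not None else _p.default_params()
    disc = disc if disc is not None else _p.default_discretization()
    return run_cases(grid.cases(), base, disc,
                     provenance=_provenance(grid, base, disc),
                     progress=progress)


def sample_cases(n: int, seed: int,
                 grid: VariationGrid | None = None,
                 base: TransportParams | None = None,
                 disc: Discretization | None = None) -> CohortDataset:
    """Simulate an independent cohort of uniformly sampled parameter triples.

    Each of the ``n`` cases draws (he, kD, kB) uniformly within the ranges
    spanned by ``grid`` (default: the canonical variation grid), emulating
    an independent set of subjects for testing the trained metric maps.
    """
    if n < 1:
        raise ParamError("need at least one sampled case")
    grid = grid if grid is not None else build_variation_grid()
    rng = np.random.default_rng(seed)
    lo = [min(grid.he_levels), min(grid.kD_levels), min(grid.kB_levels)]
    hi = [max(grid.he_levels), max(grid.kD_levels), max(grid.kB_levels)]
    triples = rng.uniform(lo, hi, size=(n, 3))
    return run_cases(
        [tuple(t) for t in triples], base, disc,
        provenance={"sampling": "uniform", "seed": seed, "n_cases": n})


def _provenance(grid: VariationGrid, base: TransportParams,
                disc: Discretization) -> dict:
    payload = {
        "grid": {"he_levels": grid.he_levels, "kD_levels": grid.kD_levels,
                 "kB_levels": grid.kB_levels},
        "params": base.to_dict(),
        "disc": disc.to_dict(),
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
    return {"config_sha256": digest, "n_cases": grid.n_cases}


def split_dataset(dataset: CohortDataset, fractions=(0.8, 0.2),
                  seed: int = 0) -> tuple[CohortDataset, CohortDataset]:
    """Reproducible disjoint train/test partition.

    ``fractions`` is (train, test), positive and summing to 1.  The test
    size is floor(n * test_fraction); the remainder trains.  Rows are
    shuffled with a seeded generator, so the same seed always yields the
    same partition.
    """
    if len(dataset) == 0:
        raise ParamError("cannot split an empty dataset")
    f_train, f_test = (float(f) for f in fractions)
    if f_train <= 0 or f_test <= 0:
        raise ParamError("both split fractions must be positive "
                         f"(got {fractions!r})")
    if abs(f_train + f_test - 1.0) > 1e-9:
        raise ParamError(f"fractions must sum to 1 (got {fractions!r})")
    n = len(dataset)
    n_test = int(np.floor(n * f_test))
    if n_test == 0 or n_test == n:
        raise ParamError(
            f"split of {n} rows with fractions {fractions!r} leaves an "
            "empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    prov = dict(dataset.provenance)
    prov["split_seed"] = seed
    train = CohortDataset(dataset.table.iloc[train_idx].reset_index(drop=True),
                          {**prov, "split": "train"})
    test = CohortDataset(dataset.table.iloc[test_idx].reset_index(drop=True),
                         {**prov, "split": "test"})
    return train, test
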