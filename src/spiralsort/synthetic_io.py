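"""Synthetic particle populations, replicate generators, and file/config I/O.

Populations emulate two sample classes: regular microspheres (circularity 1,
fixed or narrowly binned diameter) and irregular ground powders (circularity
uniform on [0.1, 1], diameter uniform on a +/- bin around the nominal size,
everything below 100 um).  Every stochastic operation takes an explicit seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .averaging_test import PRRMeasurement
from .errors import DomainError, SchemaError
from .forces import ParticleSpec
from .geometry_flow import Fluid, RectChannel
from .sorting_sim import OutletCounts
from .units import to_si

log = logging.getLogger("spiralsort")

#: hard upper size cut (um): powders are collected through a 100-um filter
MAX_DIAMETER_UM = 100.0
CIRCULARITY_RANGE = (0.1, 1.0)


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a synthetic population.

    Diameters are in um here (the unit populations are specified in); the
    generated :class:`~spiralsort.forces.ParticleSpec` objects are SI.
    """

    n: int
    nominal_diameter: float
    density: float  # g/ml
    bin_halfwidth: float = 2.0
    shape: str = "regular"  # regular | irregular
    diameter_distribution: str = "uniform_bin"  # uniform_bin | fixed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("population size must be >= 1")
        if self.bin_halfwidth < 0:
            raise DomainError("bin halfwidth must be >= 0")
        if self.density <= 0:
            raise DomainError("density must be positive")
        if self.shape not in ("regular", "irregular"):
            raise DomainError(f"shape must be 'regular' or 'irregular', got {self.shape!r}")
        if self.diameter_distribution not in ("uniform_bin", "fixed"):
            raise DomainError(
                f"diameter_distribution must be 'uniform_bin' or 'fixed', "
                f"got {self.diameter_distribution!r}"
            )
        if self.nominal_diameter - self.bin_halfwidth <= 0:
            raise DomainError(
                f"size bin [{self.nominal_diameter - self.bin_halfwidth}, "
                f"{self.nominal_diameter + self.bin_halfwidth}] um reaches zero"
            )


def generate_population(spec: PopulationSpec) -> list[ParticleSpec]:
    """Draw a deterministic (seeded) population from the spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.diameter_distribution == "fixed":
        diam_um = np.full(spec.n, spec.nominal_diameter)
    else:
        lo = spec.nominal_diameter - spec.bin_halfwidth
        hi = min(spec.nominal_diameter + spec.bin_halfwidth, MAX_DIAMETER_UM)
        diam_um = rng.uniform(lo, hi, size=spec.n)
    if spec.shape == "irregular":
        circ = rng.uniform(*CIRCULARITY_RANGE, size=spec.n)
    else:
        circ = np.ones(spec.n)
    rho_si = spec.density * 1000.0
    return [
        ParticleSpec(diameter=d * 1e-6, density=rho_si, circularity=c, label=spec.shape)
        for d, c in zip(diam_um, circ)
    ]


def generate_prr_replicates(
    true_hprr: float, sd: float, n_replicates: int, seed: int, test_diameter: float = 0.0
) -> PRRMeasurement:
    """Normal replicate hPRRs around ``true_hprr``, clipped to [0, 100]%."""
    if not 0.0 <= true_hprr <= 100.0:
        raise DomainError(f"true hPRR {true_hprr} outside [0, 100]%")
    if sd < 0:
        raise DomainError("sd must be >= 0")
    if n_replicates < 2:
        raise DomainError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    reps = np.clip(rng.normal(true_hprr, sd, size=n_replicates), 0.0, 100.0)
    return PRRMeasurement(test_diameter=test_diameter, replicate_hprrs=reps.tolist())


# --- counts I/O --------------------------------------------------------------

def read_counts(path: str | Path, n_outlets: int | None = None) -> OutletCounts:
    """Read an ``outlet,count`` CSV with strict schema validation."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a parseable counts CSV ({exc})") from exc
    if list(df.columns) != ["outlet", "count"]:
        raise SchemaError(
            f"{path}: expected columns ['outlet', 'count'], got {list(df.columns)}"
        )
    if len(df) == 0:
        raise SchemaError(f"{path}: no count rows")
    for i, row in df.iterrows():
        for col in ("outlet", "count"):
            val = row[col]
            try:
                if pd.isna(val) or float(val) != int(val):
                    raise ValueError
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: row {i + 1}: {col}={val!r} is not an integer"
                ) from None
        if int(row["count"]) < 0:
            raise SchemaError(f"{path}: row {i + 1}: negative count {row['count']}")
    outlets = df["outlet"].astype(int).tolist()
    expected_n = n_outlets if n_outlets is not None else len(outlets)
    if sorted(outlets) != list(range(1, expected_n + 1)):
        raise SchemaError(
            f"{path}: outlet column must be a contiguous 1..{expected_n}, got {outlets}"
        )
    counts = df.sort_values("outlet")["count"].astype(int).tolist()
    return OutletCounts(counts)


def write_counts(counts: OutletCounts, path: str | Path) -> None:
    df = pd.DataFrame(
        {"outlet": range(1, counts.n_outlets + 1), "count": list(counts.counts)}
    )
    df.to_csv(path, index=False)


# --- population I/O ----------------------------------------------------------

_POP_COLUMNS = ["diameter_um", "density_g_per_ml", "circularity"]


def write_population(particles: list[ParticleSpec], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "diameter_um": [p.diameter * 1e6 for p in particles],
            "density_g_per_ml": [p.density / 1000.0 for p in particles],
            "circularity": [p.circularity for p in particles],
        }
    )
    df.to_csv(path, index=False)


def read_population(path: str | Path) -> list[ParticleSpec]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a parseable population CSV ({exc})") from exc
    if list(df.columns) != _POP_COLUMNS:
        raise SchemaError(f"{path}: expected columns {_POP_COLUMNS}, got {list(df.columns)}")
    return [
        ParticleSpec(
            diameter=row.diameter_um * 1e-6,
            density=row.density_g_per_ml * 1000.0,
            circularity=row.circularity,
        )
        for row in df.itertuples()
    ]


# --- PRR replicate table I/O -------------------------------------------------

_PRR_COLUMNS = ["diameter_um", "replicate", "outlet", "hprr_percent"]


def read_prr_table(path: str | Path) -> dict[float, PRRMeasurement]:
    """Read a replicate table into one measurement per test diameter."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a parseable PRR CSV ({exc})") from exc
    if list(df.columns) != _PRR_COLUMNS:
        raise SchemaError(f"{path}: expected columns {_PRR_COLUMNS}, got {list(df.columns)}")
    out: dict[float, PRRMeasurement] = {}
    for diam, group in df.groupby("diameter_um"):
        outlets = group["outlet"].unique()
        out[float(diam)] = PRRMeasurement(
            test_diameter=float(diam),
            replicate_hprrs=group["hprr_percent"].tolist(),
            outlet=int(outlets[0]) if len(outlets) == 1 else None,
        )
    if not out:
        raise SchemaError(f"{path}: no measurement rows")
    return out


# --- device config -----------------------------------------------------------

def _si(node: dict, key: str) -> float:
    try:
        entry = node[key]
        return to_si(entry["value"], entry["unit"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"config key {key!r} must be an object {{value, unit}}") from exc


def load_device(path: str | Path) -> tuple[RectChannel, Fluid]:
    """Load a YAML/JSON device+fluid config into SI domain objects."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    channel = RectChannel(
        width=_si(doc, "width"),
        height=_si(doc, "height"),
        spiral_radius=_si(doc, "spiral_radius"),
        n_loops=int(doc.get("n_loops", 10)),
        loop_spacing=_si(doc, "loop_spacing") if "loop_spacing" in doc else 300e-6,
        n_outlets=int(doc.get("n_outlets", 5)),
        outlet_width=_si(doc, "outlet_width") if "outlet_width" in doc else 0.0,
    )
    fluid_node = doc.get("fluid")
    if not isinstance(fluid_node, dict):
        raise SchemaError(f"{path}: config must contain a 'fluid' mapping")
    fluid = Fluid(
        density=_si(fluid_node, "density"),
        viscosity=_si(fluid_node, "viscosity"),
    )
    log.info(
        "loaded device config %s: %s",
        path,
        json.dumps(
            {
                "width_m": channel.width,
                "height_m": channel.height,
                "spiral_radius_m": channel.spiral_radius,
                "n_outlets": channel.n_outlets,
                "fluid_density_kg_m3": fluid.density,
                "fluid_viscosity_pa_s": fluid.viscosity,
            }
        ),
    )
    return channel, fluid
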