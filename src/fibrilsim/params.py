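"""Parameter tables for the coarse-grained force field.

The model is a square-well/hard-sphere (discontinuous) force field over four
beads per residue: backbone united atoms NH, CA, CO and one side-chain sphere
SC.  All numeric parameters live in three human-readable YAML files with a
versioned schema:

* ``geometry.yaml`` — bead diameters, pseudo-bond lengths, squeeze factors;
* ``wells.yaml``    — the 20x20 side-chain square-well depth/range matrices;
* ``run.yaml``      — hydrogen-bond parameters, biases and engine options.

The hydrogen-bond well depth ε_HB is the energy unit (ε_HB ≡ 1), so the
reduced temperature is T* = k_B·T/ε_HB and all well depths are expressed in
ε_HB units.  The shipped defaults are documented PRIME20-convention stand-ins,
not fitted values; every entry can be overridden by editing the files.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import yaml

from ._amino import (
    AA_CODES,
    AA_INDEX,
    N_AA,
    ca_sc_bond,
    pair_well_depth,
    sidechain_diameter,
)

GEOMETRY_SCHEMA = "fibrilsim-geometry-1"
WELLS_SCHEMA = "fibrilsim-wells-1"
RUN_SCHEMA = "fibrilsim-run-1"

BEAD_KINDS = ("NH", "CA", "CO", "SC")

# Canonical backbone internal coordinates (Å / degrees).  The pseudo-bond
# lengths below are *derived* from these and stored explicitly in the table so
# that the chain builder and the bond constraints are self-consistent.
BOND_NH_CA = 1.46
BOND_CA_CO = 1.51
BOND_CO_NH = 1.33
ANGLE_NH_CA_CO = 111.0
ANGLE_CA_CO_NH = 116.0
ANGLE_CO_NH_CA = 122.0


class ParameterError(ValueError):
    """Raised when a parameter table fails validation."""


def _law_of_cosines(b1: float, b2: float, angle_deg: float) -> float:
    a = np.deg2rad(angle_deg)
    return float(np.sqrt(b1 * b1 + b2 * b2 - 2.0 * b1 * b2 * np.cos(a)))


def _sidechain_frame_distances(aa: str) -> tuple[float, float]:
    """(NH-SC, CO-SC) pseudo-bond lengths from the canonical residue frame.

    The SC centroid is placed along the standard C-beta direction of an
    L-amino acid: from CA, away from the NH/CO bisector and tilted toward the
    NH×CO normal.  Mirroring through the backbone plane would produce the
    D-isomer, which the resulting three-distance constraint set excludes.
    """
    ang = np.deg2rad(ANGLE_NH_CA_CO)
    nh = np.array([BOND_NH_CA, 0.0, 0.0])
    co = BOND_CA_CO * np.array([np.cos(ang), np.sin(ang), 0.0])
    u1 = nh / np.linalg.norm(nh)
    u2 = co / np.linalg.norm(co)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    direction = -0.536 * u1 - 0.536 * u2 + 0.652 * perp
    direction /= np.linalg.norm(direction)
    sc = ca_sc_bond(aa) * direction
    return float(np.linalg.norm(sc - nh)), float(np.linalg.norm(sc - co))


@dataclasses.dataclass
class InteractionTable:
    """Validated force-field table (energies in ε_HB, distances in Å)."""

    # hard-sphere diameters
    backbone_diameters: dict[str, float]          # NH / CA / CO
    sc_diameters: np.ndarray                      # (20,) by AA_CODES order
    # bonded geometry
    bond_lengths: dict[str, float]                # backbone + pseudo bonds
    ca_sc: np.ndarray                             # (20,) CA-SC pseudo-bond
    nh_sc: np.ndarray                             # (20,)
    co_sc: np.ndarray                             # (20,)
    bond_tolerance: float                         # fractional δ on all bonds
    # steric overrides
    squeeze_factor: float                         # SC vs neighbouring backbone
    local_backbone_factor: float                  # 1-2 bonded-neighbour backbone
    # side-chain wells
    sc_well_depth: np.ndarray                     # (20,20) ε_HB, >0 attractive
    sc_well_range: np.ndarray                     # (20,20) Å outer radius
    # hydrogen bond
    eps_hb: float
    hb_range: float
    hb_core_factor: float
    hb_aux_min: float
    hb_aux_max: float
    hb_min_same_chain_sep: int
    # biases
    salt_bridge_factor: float
    salt_bridge_pair: tuple[int, int]             # residue numbers (e.g. 23, 28)
    parallel_preference: bool
    parallel_max_angle_deg: float
    # thermostat / units
    ghost_rate: float                             # kicks per bead per τ
    reference_sigma: float                        # Å, reduced-time length unit

    def __post_init__(self) -> None:
        self.sc_diameters = np.asarray(self.sc_diameters, dtype=float)
        self.sc_well_depth = np.asarray(self.sc_well_depth, dtype=float)
        self.sc_well_range = np.asarray(self.sc_well_range, dtype=float)
        self.ca_sc = np.asarray(self.ca_sc, dtype=float)
        self.nh_sc = np.asarray(self.nh_sc, dtype=float)
        self.co_sc = np.asarray(self.co_sc, dtype=float)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.sc_well_depth.shape != (N_AA, N_AA):
            raise ParameterError("side-chain well matrix must be 20x20")
        if self.sc_well_range.shape != (N_AA, N_AA):
            raise ParameterError("side-chain range matrix must be 20x20")
        if not np.allclose(self.sc_well_depth, self.sc_well_depth.T):
            i, j = np.unravel_index(
                np.argmax(abs(self.sc_well_depth - self.sc_well_depth.T)),
                self.sc_well_depth.shape,
            )
            raise ParameterError(
                f"well-depth matrix is not symmetric at pair "
                f"{AA_CODES[i]}-{AA_CODES[j]}"
            )
        if not np.allclose(self.sc_well_range, self.sc_well_range.T):
            i, j = np.unravel_index(
                np.argmax(abs(self.sc_well_range - self.sc_well_range.T)),
                self.sc_well_range.shape,
            )
            raise ParameterError(
                f"well-range matrix is not symmetric at pair "
                f"{AA_CODES[i]}-{AA_CODES[j]}"
            )
        hd = self.sc_pair_core()
        bad = (self.sc_well_range <= hd) & (abs(self.sc_well_depth) > 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParameterError(
                f"well range does not exceed hard diameter for pair "
                f"{AA_CODES[i]}-{AA_CODES[j]}"
            )
        if (self.sc_well_range <= 0).any():
            raise ParameterError("well ranges must be positive")
        for k, d in self.backbone_diameters.items():
            if d <= 0:
                raise ParameterError(f"non-positive diameter for {k}")
        if not 0.0 < self.bond_tolerance < 0.1:
            raise ParameterError("bond tolerance must be in (0, 0.1)")
        if not 0.0 < self.squeeze_factor <= 1.0:
            raise ParameterError("squeeze factor must be in (0, 1]")
        if self.eps_hb != 1.0:
            raise ParameterError("eps_hb defines the energy unit and must be 1")
        if self.hb_range <= 0:
            raise ParameterError("hb_range must be positive")
        if self.salt_bridge_factor < 1.0:
            raise ParameterError("salt-bridge factor must be >= 1")

    # -- derived helpers --------------------------------------------------
    def sc_pair_core(self) -> np.ndarray:
        """20x20 SC-SC hard-contact distance matrix."""
        return 0.5 * (self.sc_diameters[:, None] + self.sc_diameters[None, :])

    def backbone_pair_core(self, kind_a: str, kind_b: str) -> float:
        return 0.5 * (
            self.backbone_diameters[kind_a] + self.backbone_diameters[kind_b]
        )

    def sc_backbone_core(self, aa: str, kind: str) -> float:
        return 0.5 * (
            self.sc_diameters[AA_INDEX[aa]] + self.backbone_diameters[kind]
        )

    def squeeze_distance(self, aa: str, kind: str) -> float:
        """Minimum SC-to-neighbouring-backbone distance (the squeeze)."""
        return self.squeeze_factor * self.sc_backbone_core(aa, kind)

    def hb_core(self) -> float:
        return self.hb_core_factor * self.backbone_pair_core("NH", "CO")

    def max_interaction_range(self) -> float:
        return float(
            max(self.sc_well_range.max(), self.hb_range,
                max(self.bond_lengths.values()) * (1 + self.bond_tolerance))
        )

    def unbiased(self) -> "InteractionTable":
        """Copy with the salt-bridge enhancement and parallel bias switched off."""
        return dataclasses.replace(
            self, salt_bridge_factor=1.0, parallel_preference=False
        )


# ---------------------------------------------------------------------------
# default tables


def default_geometry() -> dict:
    residues = {}
    for aa in AA_CODES:
        if aa == "G":
            residues[aa] = {
                "sc_diameter": sidechain_diameter(aa),
                "ca_sc": 0.0, "nh_sc": 0.0, "co_sc": 0.0,
            }
            continue
        nh_sc, co_sc = _sidechain_frame_distances(aa)
        residues[aa] = {
            "sc_diameter": round(sidechain_diameter(aa), 4),
            "ca_sc": round(ca_sc_bond(aa), 4),
            "nh_sc": round(nh_sc, 4),
            "co_sc": round(co_sc, 4),
        }
    return {
        "schema": GEOMETRY_SCHEMA,
        "backbone": {
            "diameters": {"NH": 3.3, "CA": 3.7, "CO": 4.0},
            "bonds": {
                "nh_ca": BOND_NH_CA,
                "ca_co": BOND_CA_CO,
                "co_nh_next": BOND_CO_NH,
                "nh_co": round(_law_of_cosines(BOND_NH_CA, BOND_CA_CO,
                                               ANGLE_NH_CA_CO), 4),
                "ca_nh_next": round(_law_of_cosines(BOND_CA_CO, BOND_CO_NH,
                                                    ANGLE_CA_CO_NH), 4),
                "co_ca_next": round(_law_of_cosines(BOND_CO_NH, BOND_NH_CA,
                                                    ANGLE_CO_NH_CA), 4),
                "ca_ca_next": 3.80,
            },
        },
        "squeeze_factor": 0.70,
        "local_backbone_factor": 0.65,
        "residues": residues,
    }


def default_wells(range_factor: float = 1.55) -> dict:
    depth = np.zeros((N_AA, N_AA))
    rng = np.zeros((N_AA, N_AA))
    for i, a in enumerate(AA_CODES):
        for j, b in enumerate(AA_CODES):
            depth[i, j] = pair_well_depth(a, b)
            core = 0.5 * (sidechain_diameter(a) + sidechain_diameter(b))
            rng[i, j] = round(range_factor * core, 4)
    return {
        "schema": WELLS_SCHEMA,
        "order": AA_CODES,
        "depth": depth.tolist(),
        "range": rng.tolist(),
    }


def default_run_options() -> dict:
    return {
        "schema": RUN_SCHEMA,
        "eps_hb": 1.0,
        "hydrogen_bond": {
            "range": 5.0,
            "core_factor": 0.75,
            "aux_min": 3.0,
            "aux_max": 6.8,
            "min_same_chain_sep": 4,
        },
        "salt_bridge": {"factor": 2.0, "residues": [23, 28]},
        "parallel_preference": {"enabled": True, "max_angle_deg": 90.0},
        "bond_tolerance": 0.015,
        "thermostat": {"ghost_rate": 0.1},
        "reference_sigma": 3.7,
    }


def _table_from_dicts(geo: dict, wells: dict, run: dict) -> InteractionTable:
    for d, schema, name in (
        (geo, GEOMETRY_SCHEMA, "geometry"),
        (wells, WELLS_SCHEMA, "wells"),
        (run, RUN_SCHEMA, "run options"),
    ):
        if d.get("schema") != schema:
            raise ParameterError(f"unrecognized {name} schema: {d.get('schema')!r}")
    order = wells["order"]
    if order != AA_CODES:
        raise ParameterError("wells matrix order must follow " + AA_CODES)
    res = geo["residues"]
    missing = sorted(set(AA_CODES) - set(res))
    if missing:
        raise ParameterError(f"geometry missing residues {missing}")
    hb = run["hydrogen_bond"]
    sb = run["salt_bridge"]
    pp = run["parallel_preference"]
    return InteractionTable(
        backbone_diameters=dict(geo["backbone"]["diameters"]),
        sc_diameters=np.array([res[a]["sc_diameter"] for a in AA_CODES]),
        bond_lengths=dict(geo["backbone"]["bonds"]),
        ca_sc=np.array([res[a]["ca_sc"] for a in AA_CODES]),
        nh_sc=np.array([res[a]["nh_sc"] for a in AA_CODES]),
        co_sc=np.array([res[a]["co_sc"] for a in AA_CODES]),
        bond_tolerance=float(run["bond_tolerance"]),
        squeeze_factor=float(geo["squeeze_factor"]),
        local_backbone_factor=float(geo["local_backbone_factor"]),
        sc_well_depth=np.array(wells["depth"]),
        sc_well_range=np.array(wells["range"]),
        eps_hb=float(run["eps_hb"]),
        hb_range=float(hb["range"]),
        hb_core_factor=float(hb["core_factor"]),
        hb_aux_min=float(hb["aux_min"]),
        hb_aux_max=float(hb["aux_max"]),
        hb_min_same_chain_sep=int(hb["min_same_chain_sep"]),
        salt_bridge_factor=float(sb["factor"]),
        salt_bridge_pair=(int(sb["residues"][0]), int(sb["residues"][1])),
        parallel_preference=bool(pp["enabled"]),
        parallel_max_angle_deg=float(pp["max_angle_deg"]),
        ghost_rate=float(run["thermostat"]["ghost_rate"]),
        reference_sigma=float(run["reference_sigma"]),
    )


def default_table() -> InteractionTable:
    """The shipped default table (PRIME20-convention stand-in values)."""
    return _table_from_dicts(default_geometry(), default_wells(),
                             default_run_options())


def _data_dir() -> Path:
    return Path(str(importlib.resources.files("fibrilsim") / "data"))


def load_parameter_tables(
    config_dir: str | Path | None = None,
    geometry: str = "geometry.yaml",
    wells: str = "wells.yaml",
    run: str = "run.yaml",
) -> InteractionTable:
    """Load and validate the three parameter files from *config_dir*.

    With no argument, loads the package's shipped defaults.  Missing files or
    entries, asymmetric matrices and range/diameter inversions raise
    :class:`ParameterError` naming the offending item.
    """
    base = _data_dir() if config_dir is None else Path(config_dir)
    dicts = []
    for name in (geometry, wells, run):
        path = base / name
        if not path.is_file():
            raise ParameterError(f"missing parameter file: {path}")
        with open(path) as fh:
            dicts.append(yaml.safe_load(fh))
    return _table_from_dicts(*dicts)


def write_parameter_tables(config_dir: str | Path,
                           table_dicts: tuple[dict, dict, dict] | None = None,
                           ) -> None:
    """Write geometry/wells/run YAML files (defaults if none given)."""
    base = Path(config_dir)
    base.mkdir(parents=True, exist_ok=True)
    geo, wells, run = table_dicts or (
        default_geometry(), default_wells(), default_run_options()
    )
    for name, d in (("geometry.yaml", geo), ("wells.yaml", wells),
                    ("run.yaml", run)):
        with open(base / name, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
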