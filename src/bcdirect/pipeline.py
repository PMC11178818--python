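"""End-to-end orchestration: simulate → analyze → criteria.

``simulate`` runs the toy FE model over a direction grid and frequency set
and streams the window-frame z-displacements of the rim ring and membrane
surface into a single HDF5 container (complex values stored as paired real
arrays) together with a manifest (config hash, seed, package versions).
``analyze`` turns the container into per-(direction, frequency) tables of
rim rigid motion and membrane volume displacement.  ``criteria`` reduces the
tables to the two weighted-sum criterion maps, the per-frequency weights,
and the four refined extreme directions.

Every command is a deterministic function of (config, seed), and the CLI is
a thin wrapper over these functions — results are identical to composing the
library calls directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .criteria import (
    THIRD_OCTAVE_17,
    CriterionMap,
    ResponseSurface,
    coarse_extremes,
    criterion_map,
)
from .fem import assemble, sweep
from .frames import (
    STIMULATION_FRAME,
    DirectionAngles,
    Frame,
    angle_grid,
    direction_vector,
    symmetry_image,
)
from .kinematics import build_ring, fit_ring_motion
from .refine import Stencil3x3, refine_extremum
from .synthetic import make_toy_bone
from .volume import MembraneMesh, amplitude_phase, total_vd

logger = logging.getLogger("bcdirect")


# ------------------------------------------------------------------ config

class GridSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    step_deg: float = 15.0
    lo_deg: float = -90.0
    hi_deg: float = 90.0


class FrameSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    origin_mm: list[float] = Field(default_factory=lambda: STIMULATION_FRAME.origin.tolist())
    x_hat: list[float] = Field(default_factory=lambda: STIMULATION_FRAME.x_hat.tolist())
    y_hat: list[float] = Field(default_factory=lambda: STIMULATION_FRAME.y_hat.tolist())
    z_hat: list[float] = Field(default_factory=lambda: STIMULATION_FRAME.z_hat.tolist())

    def to_frame(self) -> Frame:
        return Frame.from_raw(self.origin_mm, self.x_hat, self.y_hat, self.z_hat)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    force_amplitude_N: float = 0.1
    frequencies_hz: list[float] = Field(default_factory=lambda: list(THIRD_OCTAVE_17))
    grid: GridSpec = Field(default_factory=GridSpec)
    stimulation_frame: FrameSpec = Field(default_factory=FrameSpec)
    model: Literal["toy"] = "toy"
    output_dir: str = "bcdirect_out"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


# ----------------------------------------------------------- container I/O

def write_container(
    path,
    *,
    rw_frame: Frame,
    ring_xy: np.ndarray,
    ring_ids: np.ndarray,
    membrane_xy: np.ndarray,
    membrane_quads: np.ndarray,
    frequencies: Sequence[float],
    grid: Sequence[DirectionAngles],
    ring_wz: np.ndarray,     # (n_dir, n_freq, n_ring) complex, mm
    membrane_wz: np.ndarray, # (n_dir, n_freq, n_mem) complex, mm
    attrs: Optional[dict] = None,
) -> None:
    """Write one run's fields to the HDF5 container (complex as re/im pairs)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "bcdirect-container-v1"
        f.attrs["version"] = __version__
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        g = f.create_group("rw_frame")
        for k, v in rw_frame.to_config().items():
            g.create_dataset(k, data=np.asarray(v))
        f.create_dataset("ring/xy", data=np.asarray(ring_xy, dtype=float))
        f.create_dataset("ring/node_ids", data=np.asarray(ring_ids, dtype=int))
        f.create_dataset("membrane/xy", data=np.asarray(membrane_xy, dtype=float))
        f.create_dataset("membrane/quads", data=np.asarray(membrane_quads, dtype=int))
        f.create_dataset("frequencies_hz", data=np.asarray(frequencies, dtype=float))
        f.create_dataset("grid/alpha_deg", data=np.array([g.alpha for g in grid]))
        f.create_dataset("grid/beta_deg", data=np.array([g.beta for g in grid]))
        f.create_dataset("fields/ring_re", data=ring_wz.real)
        f.create_dataset("fields/ring_im", data=ring_wz.imag)
        f.create_dataset("fields/membrane_re", data=membrane_wz.real)
        f.create_dataset("fields/membrane_im", data=membrane_wz.imag)


def read_container(path) -> dict:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "bcdirect-container-v1":
            raise ValueError(f"{path} is not a bcdirect field container")
        out = {
            "rw_frame": Frame.from_raw(
                f["rw_frame/origin_mm"][()], f["rw_frame/x_hat"][()],
                f["rw_frame/y_hat"][()], f["rw_frame/z_hat"][()],
            ),
            "ring_xy": f["ring/xy"][()],
            "ring_ids": f["ring/node_ids"][()],
            "membrane_xy": f["membrane/xy"][()],
            "membrane_quads": f["membrane/quads"][()],
            "frequencies": f["frequencies_hz"][()],
            "alpha_deg": f["grid/alpha_deg"][()],
            "beta_deg": f["grid/beta_deg"][()],
            "ring_wz": f["fields/ring_re"][()] + 1j * f["fields/ring_im"][()],
            "membrane_wz": f["fields/membrane_re"][()] + 1j * f["fields/membrane_im"][()],
            "attrs": dict(f.attrs),
        }
    return out


# ---------------------------------------------------------------- simulate

def _rw_projection(model, rw_frame: Frame, node_ids: np.ndarray):
    """Window-frame planar coordinates (mm) of model nodes."""
    pos_mm = model.nodes[node_ids] * 1e3 - rw_frame.origin
    return np.stack([pos_mm @ rw_frame.x_hat, pos_mm @ rw_frame.y_hat], axis=1)


def cmd_simulate(config: RunConfig, out_dir: Optional[Path] = None) -> Path:
    """Run the toy-model sweep and write the field container + manifest."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    container = out / "fields.h5"
    manifest_path = out / "manifest.json"
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bcdirect_version": __version__,
        "numpy_version": np.__version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "valid": False,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    try:
        model, rw_frame = make_toy_bone(seed=config.seed)
        frame = config.stimulation_frame.to_frame()
        grid = angle_grid(config.grid.step_deg, config.grid.lo_deg, config.grid.hi_deg)
        dirs = [direction_vector(frame, g) for g in grid]
        freqs = list(config.frequencies_hz)
        ring_ids = model.node_sets["rw_edge"]
        mem_ids = model.node_sets["rw_membrane"]
        ring_xy = _rw_projection(model, rw_frame, ring_ids)
        mem_xy = _rw_projection(model, rw_frame, mem_ids)
        quads = model.face_sets["rw_membrane_quads"]
        # remap membrane quad connectivity to positions within mem_ids
        remap = {int(n): i for i, n in enumerate(mem_ids)}
        quads_local = np.vectorize(remap.get)(quads)
        nd, nf = len(grid), len(freqs)
        ring_wz = np.zeros((nd, nf, len(ring_ids)), dtype=complex)
        mem_wz = np.zeros((nd, nf, len(mem_ids)), dtype=complex)
        ops = assemble(model)
        fidx = {float(f): i for i, f in enumerate(freqs)}
        for i_dir, f, fld in sweep(model, dirs, freqs, config.force_amplitude_N, ops=ops):
            u_mm = fld.u_mm
            ring_wz[i_dir, fidx[f]] = u_mm[ring_ids] @ rw_frame.z_hat
            mem_wz[i_dir, fidx[f]] = u_mm[mem_ids] @ rw_frame.z_hat
        write_container(
            container,
            rw_frame=rw_frame,
            ring_xy=ring_xy,
            ring_ids=ring_ids,
            membrane_xy=mem_xy,
            membrane_quads=quads_local,
            frequencies=freqs,
            grid=grid,
            ring_wz=ring_wz,
            membrane_wz=mem_wz,
            attrs={
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "force_N": config.force_amplitude_N,
                "model_hash": model.content_hash(),
            },
        )
    except Exception:
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
    manifest["valid"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("simulate: wrote %s (%d directions × %d frequencies)",
                container, nd, nf)
    return container


# ----------------------------------------------------------------- analyze

def cmd_analyze(container, csv_path=None, grouping: str = "spread") -> pd.DataFrame:
    """Per-(direction, frequency) rim motion and volume displacement table.

    Columns: alpha_deg, beta_deg, freq_hz, w_re, w_im, w_amp_mm, w_phase_deg,
    V_re, V_im, V_amp_mm3, V_phase_deg.  ``grouping`` picks the rim-triangle
    grouping ("spread" default for the toy model's 12-node square rim, whose
    consecutive triples would be collinear).
    """
    data = read_container(container)
    ring = build_ring(data["ring_ids"], data["ring_xy"])
    if grouping == "spread":
        from .kinematics import RingTriangulation

        m = len(ring.node_ids) // 3
        tris = tuple((i, i + m, i + 2 * m) for i in range(m))
        ring = RingTriangulation(node_ids=ring.node_ids, xy=ring.xy, triangles=tris)
    mesh = MembraneMesh(nodes=data["membrane_xy"], quads=data["membrane_quads"])
    # ring node order: fields are stored in ring_ids order; re-sort to match
    order = [list(data["ring_ids"]).index(n) for n in ring.node_ids]
    rows = []
    for i_dir, (a, b) in enumerate(zip(data["alpha_deg"], data["beta_deg"])):
        for i_f, f in enumerate(data["frequencies"]):
            wz = data["ring_wz"][i_dir, i_f][order]
            rm = fit_ring_motion(ring, wz)
            vd = total_vd(mesh, data["membrane_wz"][i_dir, i_f], rm)
            w_amp, w_ph = amplitude_phase(rm.w_bar)
            rows.append(
                {
                    "alpha_deg": a, "beta_deg": b, "freq_hz": f,
                    "w_re": rm.w_bar.real, "w_im": rm.w_bar.imag,
                    "w_amp_mm": w_amp, "w_phase_deg": w_ph,
                    "V_re": vd.V.real, "V_im": vd.V.imag,
                    "V_amp_mm3": vd.amplitude, "V_phase_deg": vd.phase_deg,
                }
            )
    df = pd.DataFrame(rows)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def surface_from_table(df: pd.DataFrame) -> ResponseSurface:
    """Assemble a ResponseSurface from the analyze table."""
    freqs = sorted(df["freq_hz"].unique())
    pairs = df[["alpha_deg", "beta_deg"]].drop_duplicates().to_numpy()
    angles = tuple(DirectionAngles(alpha=a, beta=b) for a, b in pairs)
    v = df.pivot_table(index=["alpha_deg", "beta_deg"], columns="freq_hz",
                       values="V_amp_mm3", sort=False)
    w = df.pivot_table(index=["alpha_deg", "beta_deg"], columns="freq_hz",
                       values="w_amp_mm", sort=False)
    key = pd.MultiIndex.from_arrays([pairs[:, 0], pairs[:, 1]])
    return ResponseSurface(
        angles=angles,
        frequencies=freqs,
        v_amp=v.loc[key, freqs].to_numpy(),
        w_amp=w.loc[key, freqs].to_numpy(),
    )


# ---------------------------------------------------------------- criteria

def _value_lookup(cmap: CriterionMap, which: str) -> dict:
    vals = cmap.v_crit if which == "V" else cmap.w_crit
    return {
        (round(g.alpha, 6), round(g.beta, 6)): float(v)
        for g, v in zip(cmap.angles, vals)
    }


def build_stencil(
    cmap: CriterionMap, which: str, center: DirectionAngles, spacing: float
) -> Stencil3x3:
    """3×3 stencil of criterion values around a grid node.

    Neighbors beyond the ±90° boundary are filled through the direction-
    symmetry map: the response amplitude at an out-of-range pair equals the
    amplitude at its in-range image (the direction vectors are equal or
    antiparallel, and amplitudes are sign-invariant under a linear model).
    """
    lut = _value_lookup(cmap, which)
    vals = np.empty((3, 3))
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            a = center.alpha + di * spacing
            b = center.beta + dj * spacing
            if abs(a) > 90.0 or abs(b) > 90.0:
                img, _sign = symmetry_image((a, b))
                a, b = img.alpha, img.beta
            key = (round(a, 6), round(b, 6))
            if key not in lut:
                raise ValueError(
                    f"stencil node ({a}, {b}) missing from the criterion map"
                )
            vals[di + 1, dj + 1] = lut[key]
    return Stencil3x3(center=center, spacing=spacing, values=vals)


def cmd_criteria(
    df: pd.DataFrame, spacing: Optional[float] = None, json_path=None
) -> tuple[CriterionMap, list[dict]]:
    """Criterion maps plus the four refined extreme directions.

    Returns (CriterionMap, records); each record is JSON-ready:
    {criterion, kind, alpha_deg, beta_deg, value, boundary_flag}.
    """
    surface = surface_from_table(df)
    cmap = criterion_map(surface)
    alphas = sorted({g.alpha for g in cmap.angles})
    if spacing is None:
        spacing = alphas[1] - alphas[0]
    records = []
    for rec in coarse_extremes(cmap):
        stencil = build_stencil(cmap, rec.criterion, rec.angles, spacing)
        refined = refine_extremum(stencil, kind=rec.kind)
        records.append(
            {
                "criterion": rec.criterion,
                "kind": rec.kind,
                "alpha_deg": refined.angles.alpha,
                "beta_deg": refined.angles.beta,
                "value": refined.value,
                "boundary_flag": bool(refined.boundary),
                "coarse_alpha_deg": rec.angles.alpha,
                "coarse_beta_deg": rec.angles.beta,
            }
        )
    if json_path is not None:
        Path(json_path).write_text(json.dumps(records, indent=2))
    return cmap, records


def export_criteria_csv(cmap: CriterionMap, path) -> None:
    pd.DataFrame(
        {
            "alpha_deg": [g.alpha for g in cmap.angles],
            "beta_deg": [g.beta for g in cmap.angles],
            "V_crit": cmap.v_crit,
            "w_crit": cmap.w_crit,
        }
    ).to_csv(path, index=False)


def plot_criterion_heatmaps(cmap: CriterionMap, path) -> None:
    """Optional heat-map rendering of both criterion maps (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    alphas = sorted({g.alpha for g in cmap.angles})
    betas = sorted({g.beta for g in cmap.angles})
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (name, vals) in zip(
        axes, (("w̄ criterion", cmap.w_crit), ("V criterion", cmap.v_crit))
    ):
        grid = np.full((len(betas), len(alphas)), np.nan)
        for g, v in zip(cmap.angles, vals):
            grid[betas.index(g.beta), alphas.index(g.alpha)] = v
        im = ax.imshow(
            grid, origin="lower", aspect="auto",
            extent=(min(alphas), max(alphas), min(betas), max(betas)),
        )
        ax.set_xlabel("alpha, deg")
        ax.set_ylabel("beta, deg")
        ax.set_title(name)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
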