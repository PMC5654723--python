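"""End-to-end orchestration: structure -> rigidity -> modes -> trajectories
-> observables, with a reproducible YAML manifest per run."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enm as enm_mod
from . import geomsim, motion, pebble, synth
from .network import build_network
from .structure import (DomainAnnotation, locate_active_sites, parse_pdb,
                        write_ensemble)

__all__ = ["RunConfig", "run_pipeline", "load_annotation_yaml", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    input_pdb: str | None = None
    synthetic: dict | None = None          # SyntheticSpec fields
    domain_table: str | dict | None = None  # YAML path or inline mapping
    hbond_distance_max: float = 3.5
    hbond_angle_min: float = 90.0
    hydrophobic_cutoff: float = 3.9
    enm_cutoff: float = 10.0
    modes: list[int] = field(default_factory=lambda: [7, 8, 9, 10, 11])
    max_conformers: int = 100
    step_size: float = geomsim.DEFAULT_STEP_SIZE
    record_every: int = 1
    clash_scale: float = geomsim.DEFAULT_CLASH_SCALE
    tol: float = geomsim.DEFAULT_TOL
    max_iter: int = geomsim.DEFAULT_MAX_ITER
    output_dir: str = "pdiflex_run"
    seed: int = 0

    def __post_init__(self):
        for m in self.modes:
            if m < 7:
                raise ValueError(
                    f"mode {m} is not an internal mode (rigid-body modes are 1-6; "
                    "internal motion starts at mode 7)")
        if self.input_pdb is None and self.synthetic is None:
            raise ValueError("config needs either input_pdb or a synthetic spec")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data.pop("package_version", None)
        return cls(**data)


def load_annotation_yaml(source) -> DomainAnnotation:
    """Domain table from YAML: {convention, offset, domains: {name: [s, e]}}."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    domains = []
    for name, ranges in data["domains"].items():
        if ranges and isinstance(ranges[0], int):
            ranges = [ranges]
        domains.append((str(name), [tuple(r) for r in ranges]))
    return DomainAnnotation(domains, data.get("convention", "mature"),
                            int(data.get("offset", 17)))


def _load_structure(config: RunConfig):
    if config.input_pdb is not None:
        structure = parse_pdb(config.input_pdb)
        if config.domain_table is None:
            raise PipelineError("stage input: a domain table is required for PDB input")
        annotation = load_annotation_yaml(config.domain_table)
    else:
        spec = synth.SyntheticSpec(**{**config.synthetic, "seed": config.seed})
        structure = synth.make_structure(spec)
        annotation = (load_annotation_yaml(config.domain_table)
                      if config.domain_table else synth.default_annotation(spec))
    return structure, annotation


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write results under ``config.output_dir``.

    Per mode and direction: a multi-model PDB trajectory; per mode: tidy
    CSVs of active-site distance, adjacent-domain midpoint distances and
    tilt/twist angles; plus rigidity CSV, summary JSON and the manifest.
    Rerunning with the same manifest reproduces identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        structure, annotation = _load_structure(config)
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc

    try:
        network = build_network(structure, config.hbond_distance_max,
                                config.hbond_angle_min, config.hydrophobic_cutoff)
        decomposition = pebble.pebble_game(network)
        pebble.decomposition_to_csv(structure, decomposition, out / "rigid_clusters.csv")
        pebble.decomposition_to_pdb(structure, decomposition, out / "rigid_clusters.pdb")
    except Exception as exc:
        raise PipelineError(f"stage rigidity: {exc}") from exc

    try:
        elastic = enm_mod.build_enm(structure, config.enm_cutoff)
        modeset = enm_mod.compute_modes(elastic, n_internal=max(config.modes) - 6)
    except Exception as exc:
        raise PipelineError(f"stage modes: {exc}") from exc

    try:
        sites = locate_active_sites(structure)
    except Exception:
        sites = None

    ghosts = geomsim.build_ghosts(structure, decomposition, network)
    domain_names = annotation.domain_names()
    interfaces = list(zip(domain_names, domain_names[1:]))
    summary: dict = {"source": structure.source_id,
                     "n_atoms": len(structure.atoms),
                     "n_clusters": decomposition.n_clusters(),
                     "floppy_modes": decomposition.floppy_modes,
                     "n_zero_modes": modeset.n_zero,
                     "modes": {}}
    series_by_interface = {i: [] for i in interfaces}

    for m in config.modes:
        try:
            vec = modeset.mode(m)
            runs = {}
            for direction in ("+", "-"):
                runs[direction] = geomsim.run_trajectory(
                    structure, vec, direction, ghosts=ghosts,
                    max_conformers=config.max_conformers, step_size=config.step_size,
                    record_every=config.record_every, clash_scale=config.clash_scale,
                    tol=config.tol, max_iter=config.max_iter, mode_index=m)
                write_ensemble(runs[direction], out / f"mode{m}_{'pos' if direction == '+' else 'neg'}.pdb")
            traj = geomsim.combine_directions(runs["+"], runs["-"])
        except Exception as exc:
            raise PipelineError(f"stage simulate (mode {m}): {exc}") from exc

        try:
            frames = []
            if sites is not None:
                ds = motion.pair_distance(traj, (*sites.site_a, "CA"),
                                          (*sites.site_a_prime, "CA"))
                idx, vals = ds.as_arrays()
                frames.append(pd.DataFrame({"conformer": idx, "observable": ds.label,
                                            "value": vals}))
                summary["modes"].setdefault(str(m), {})["active_site_distance"] = {
                    "min": ds.min(), "max": ds.max()}
            for d1, d2 in interfaces:
                ds = motion.domain_midpoint_distance(traj, d1, d2, annotation)
                idx, vals = ds.as_arrays()
                frames.append(pd.DataFrame({"conformer": idx, "observable": ds.label,
                                            "value": vals}))
            if frames:
                pd.concat(frames).to_csv(out / f"mode{m}_distances.csv", index=False)

            tt_frames = []
            for interface in interfaces:
                s = motion.tilt_twist(traj, interface, annotation)
                series_by_interface[interface].append(s)
                idx = sorted(s.tilt)
                tt_frames.append(pd.DataFrame({
                    "conformer": idx,
                    "interface": f"{interface[0]}-{interface[1]}",
                    "tilt": [s.tilt[i] for i in idx],
                    "twist": [s.twist[i] for i in idx]}))
            if tt_frames:
                pd.concat(tt_frames).to_csv(out / f"mode{m}_tilt_twist.csv", index=False)
        except Exception as exc:
            raise PipelineError(f"stage analyse (mode {m}): {exc}") from exc

        summary["modes"].setdefault(str(m), {})
        summary["modes"][str(m)]["halt_pos"] = traj.halt_reason_pos
        summary["modes"][str(m)]["halt_neg"] = traj.halt_reason_neg

    if interfaces:
        report = motion.interface_mobility_summary(series_by_interface)
        summary["interface_mobility"] = [
            {**r, "interface": f"{r['interface'][0]}-{r['interface'][1]}"} for r in report]

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    manifest = asdict(config)
    from . import __version__
    manifest["package_version"] = __version__
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
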