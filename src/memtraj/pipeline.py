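"""Pipeline orchestration: run analysis stages from a config and emit reports.

Reports are CSV/TSV files with ``#``-prefixed metadata header lines (frame
count, stride, cutoffs), so each table is self-describing: occupancy
percentages are meaningless without the frame normalisation they were
computed under.  A JSON manifest records parameters, seed and version so a
run can be reproduced bit-identically; no timestamps are written, and the
same config + seed produce byte-identical report bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .system import (
    AnalysisParameters,
    MolecularSystem,
    RegionDefinition,
    load_system,
    select_atoms,
)
from .contacts import (
    ContactSeries,
    OccupancyReport,
    motif_occupancy_classes,
    occupancy_percent,
    occupancy_report,
    region_contact_series,
)
from .fingerprint import FingerprintReport, fingerprint_report
from .metrics import bend_profile, pca_modes, rmsd_series, rmsf_profile
from .motifs import find_named_motifs, read_fasta, write_motif_report
from .synthetic import SyntheticSpec, demo_apo_spec, demo_holo_spec, synthesize_trajectory

log = logging.getLogger("memtraj")

STAGES = ("motifs", "contacts", "fingerprint", "metrics", "simulate")


@dataclass
class RunConfig:
    """What to run and on which inputs."""

    stages: tuple = ("simulate", "contacts")
    output_dir: Path = Path("memtraj_out")
    seed: int = 0
    system_label: str = "system"
    structure: Path | None = None
    trajectory: Path | None = None
    fasta: Path | None = None
    regions_path: Path | None = None
    params: AnalysisParameters = field(default_factory=AnalysisParameters)
    synthetic: object = "apo"  # "apo" | "holo" | SyntheticSpec, for the simulate stage
    n_frames: int = 1000
    motif_pair: tuple = ("CRAC", "CARC")
    hbond_pairs: dict = field(default_factory=dict)  # label -> (donor, acceptor) specs
    stride_ns: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _resolve_regions(config: RunConfig) -> RegionDefinition:
    if config.regions_path is not None:
        return RegionDefinition.from_yaml(config.regions_path)
    return RegionDefinition.default_htspo()


def _resolvable_regions(system: MolecularSystem, regions: RegionDefinition) -> list:
    """Regions whose residue ranges exist in the system's protein."""
    prot = set()
    for mol in system.molecules_of_class("protein"):
        prot.update(int(r) for r in system.resids[system.atoms_of_molecule(mol)])
    out = []
    for name in regions.names():
        reg = regions[name]
        if all(r in prot for r in range(reg.start, reg.end + 1)):
            out.append(reg)
        else:
            log.info("skipping region %r: residues absent from the structure", name)
    return out


#: public name for the region filter (loop regions are absent from synthetic bundles)
resolvable_regions = _resolvable_regions


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; write the report bundle.

    Returns the in-memory results ({"system", "truth", "occupancy", ...}).
    Dependency problems (e.g. contacts without a structure or simulate stage)
    are detected before any computation.
    """
    stages = list(config.stages)
    needs_system = any(s in stages for s in ("contacts", "fingerprint", "metrics"))
    if needs_system and "simulate" not in stages and config.structure is None:
        raise ValueError(
            "stages need a system: provide a structure/trajectory or add the "
            "'simulate' stage"
        )
    if "motifs" in stages and config.fasta is None:
        raise ValueError("motifs stage needs a FASTA input")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = _resolve_regions(config)
    params = config.params
    results: dict = {}

    if "motifs" in stages:
        log.info("stage motifs: scanning %s", config.fasta)
        seqs = read_fasta(config.fasta)
        motif_results = {s.id: find_named_motifs(s, regions) for s in seqs}
        for s in seqs:
            write_motif_report(motif_results[s.id], out / f"motifs_{s.id.replace('|', '_')}.tsv",
                               sequence_id=s.id)
        results["motifs"] = motif_results

    system = None
    truth = None
    if "simulate" in stages:
        spec = config.synthetic
        if spec == "apo":
            spec = demo_apo_spec(config.n_frames)
        elif spec == "holo":
            spec = demo_holo_spec(config.n_frames)
        elif not isinstance(spec, SyntheticSpec):
            raise ValueError("synthetic must be 'apo', 'holo' or a SyntheticSpec")
        log.info("stage simulate: %d frames, seed %d", spec.n_frames, config.seed)
        system, truth = synthesize_trajectory(spec, seed=config.seed, regions=regions)
        results["system"], results["truth"] = system, truth
        _write_ground_truth(truth, out / "ground_truth.json")
    elif config.structure is not None and needs_system:
        log.info("loading %s", config.structure)
        system = load_system(config.structure, config.trajectory, stride_ns=config.stride_ns)
        results["system"] = system

    if "contacts" in stages:
        usable = _resolvable_regions(system, regions)
        log.info("stage contacts: %d regions, %d frames", len(usable), system.n_frames)
        series = region_contact_series(system, usable, cutoff=params.cholesterol_cutoff)
        pair = config.motif_pair if all(m in series.region_names for m in config.motif_pair) else None
        report = occupancy_report(series, config.system_label, motif_pair=pair)
        results["contact_series"] = series
        results["occupancy"] = report
        write_occupancy_table([report], out / "occupancy.csv")
        if pair:
            craclike = (
                occupancy_percent(series, "CRAC-like") if "CRAC-like" in series.region_names
                else None
            )
            _write_motif_classes(report, craclike, out / "motif_classes.csv")
        labels_path = out / "motif_class_trace.tsv"
        if pair:
            labels, _ = motif_occupancy_classes(series, *pair)
            _write_class_trace(series, labels, labels_path)

    if "fingerprint" in stages:
        if not system.molecules_of_class("ligand"):
            raise ValueError("fingerprint stage: no molecule of class 'ligand' in the system")
        log.info("stage fingerprint: %d frames", system.n_frames)
        fp = fingerprint_report(system, params, hbond_pairs=config.hbond_pairs)
        results["fingerprint"] = fp
        _write_fingerprint(fp, system, out / "fingerprint.csv")

    if "metrics" in stages:
        log.info("stage metrics: %d frames", system.n_frames)
        results["metrics"] = _run_metrics(system, regions, params, out)

    _write_manifest(config, system, out / "manifest.json")
    return results


def _run_metrics(system, regions, params, out: Path) -> dict:
    lo, hi = params.rmsd_selection
    prot_resids = sorted(
        {int(r) for m in system.molecules_of_class("protein")
         for r in system.resids[system.atoms_of_molecule(m)]}
    )
    lo = max(lo, prot_resids[0])
    hi = min(hi, prot_resids[-1])
    bb = select_atoms(system, resid_range=(lo, hi), molecule_class="protein",
                      backbone=True, heavy_only=True)
    rmsd = rmsd_series(system, bb)
    _write_series_csv(out / "rmsd.csv", "frame,time_ns,rmsd_A",
                      [(f, system.times[f], rmsd[f]) for f in range(len(rmsd))],
                      meta={"selection": f"backbone {lo}-{hi}"})

    ca = select_atoms(system, resid_range=(lo, hi), molecule_class="protein", names=("CA",))
    window = (params.equilibration_start_ns, float(system.times[-1]))
    if window[0] >= window[1]:
        window = None  # short trajectories: fall back to the full range
    rmsf = rmsf_profile(system, ca, window=window)
    resids = system.resids[ca]
    _write_series_csv(out / "rmsf.csv", "resid,rmsf_A",
                      list(zip(resids.tolist(), rmsf.tolist())),
                      meta={"window_ns": str(window)})

    pca = pca_modes(system, ca, window=window)
    _write_series_csv(out / "pca_eigenvalues.csv", "mode,eigenvalue_A2",
                      list(enumerate(pca.eigenvalues[:20].tolist())),
                      meta={"selection": f"CA {lo}-{hi}"})

    bends = {}
    for name in regions.names():
        reg = regions[name]
        if not name.startswith("TM"):
            continue
        try:
            prof = bend_profile(system, (reg.start, reg.end),
                                bin_edges=params.bend_bins)
        except ValueError:
            continue
        bends[name] = prof
        rows = []
        for f in range(prof.angles.shape[0]):
            for p in range(prof.angles.shape[1]):
                rows.append((f, f"{prof.positions[p]:.1f}", f"{prof.angles[f, p]:.3f}",
                             prof.labels[f, p]))
        _write_series_csv(out / f"bend_{name.replace(' ', '_')}.csv",
                          "frame,position,angle_deg,bin", rows,
                          meta={"bin_edges_deg": ",".join(map(str, params.bend_bins))})
    return {"rmsd": rmsd, "rmsf": rmsf, "pca": pca, "bends": bends,
            "rmsf_resids": resids}


# ---------------------------------------------------------------------------
# writers


def _meta_lines(pairs: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in pairs.items())


def write_occupancy_table(reports, path) -> None:
    """Occupancy CSV: systems as rows, TM I-TM V as columns, 1-decimal percent."""
    reports = list(reports)
    helix_cols = [n for n in reports[0].percent if n.startswith("TM")]
    meta = {
        "quantity": "percent of frames with >= 1 bound cholesterol",
        "cutoff_A": reports[0].cutoff,
        "frame_count": reports[0].frame_count,
        "stride_ns": reports[0].stride_ns,
        "note": "a molecule bound to two helices counts once per helix",
    }
    lines = [_meta_lines(meta) + "system," + ",".join(helix_cols)]
    for rep in reports:
        lines.append(rep.system_label + "," + ",".join(f"{rep.percent[c]:.1f}" for c in helix_cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_occupancy_table(path) -> dict:
    """Parse an occupancy CSV back into {system: {helix: percent}}."""
    rows = [l for l in Path(path).read_text().splitlines() if l and not l.startswith("#")]
    header = rows[0].split(",")[1:]
    out = {}
    for row in rows[1:]:
        parts = row.split(",")
        out[parts[0]] = {h: float(v) for h, v in zip(header, parts[1:])}
    return out


def _write_motif_classes(report: OccupancyReport, craclike_percent, path) -> None:
    meta = {
        "quantity": "frame counts of paired-motif occupancy classes",
        "frame_count": report.frame_count,
        "simultaneous_rule": "two distinct molecules, one per motif; lone bridgers excluded",
    }
    cols = ["none", "only_a", "only_b", "simultaneous", "bridged_only"]
    lines = [_meta_lines(meta) + ",".join(["system"] + cols + ["craclike_occupied_percent"])]
    cl = "" if craclike_percent is None else f"{craclike_percent:.1f}"
    lines.append(",".join([report.system_label]
                          + [str(report.motif_classes.get(c, 0)) for c in cols] + [cl]))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_class_trace(series: ContactSeries, labels, path) -> None:
    lines = ["frame\ttime_ns\tclass"]
    for f in range(series.frame_count):
        lines.append(f"{f}\t{series.times[f]}\t{labels[f]}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_fingerprint(fp: FingerprintReport, system, path) -> None:
    meta = {
        "cutoff_A": fp.cutoff,
        "window_ns": str(fp.window),
        "classes": "constant >= 0.90 (inclusive), frequent >= 0.75, transient > 0",
    }
    lines = [_meta_lines(meta) + "resid,fraction,class"]
    for resid in sorted(fp.fractions):
        lines.append(f"{resid},{fp.fractions[resid]:.4f},{fp.classes[resid]}")
    for label, occ in fp.hbonds.items():
        lines.append(f"# hbond {label}: {occ:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_series_csv(path, header: str, rows, meta: dict | None = None) -> None:
    lines = []
    if meta:
        lines.append(_meta_lines(meta) + header)
    else:
        lines.append(header)
    for row in rows:
        lines.append(",".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_ground_truth(truth, path) -> None:
    payload = {
        "region_names": truth.region_names,
        "occupancy_fraction": truth.occupancy_fraction,
        "mean_bound": truth.mean_bound,
        "bound_events": truth.bound_events,
        "ligand_fractions": {str(k): v for k, v in truth.ligand_fractions.items()},
        "hbond_fraction": truth.hbond_fraction,
        "kink_angles": {str(k): v for k, v in truth.kink_angles.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _write_manifest(config: RunConfig, system, path) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "system_label": config.system_label,
        "parameters": asdict(config.params),
        "frame_count": None if system is None else system.n_frames,
        "stride_ns": (
            None if system is None or system.n_frames < 2
            else float(np.median(np.diff(system.times)))
        ),
        "inputs": {
            "structure": str(config.structure) if config.structure else None,
            "trajectory": str(config.trajectory) if config.trajectory else None,
            "fasta": str(config.fasta) if config.fasta else None,
            "synthetic": config.synthetic if isinstance(config.synthetic, str) else "custom",
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
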