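"""End-to-end analysis runs: configuration, orchestration, TSV reports.

Each ``run_*`` function reads structures, executes one analysis stage and
writes machine-readable TSV outputs plus a RunReport manifest.  Reruns
with an identical configuration and seed are byte-identical.  Computation
is in Å; report columns are duplicated in nm where principal dimensions
are conventionally quoted in nm.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coil_geometry, contacts, domain_geometry, model_builder
from .structure_io import (
    COIL_SUBDOMAINS, HEAD_SUBDOMAINS, TAIL_SUBDOMAINS,
    Ensemble, SubdomainAnnotation,
    default_annotation, load_annotation, read_pdb, write_pdb,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_geometry", "run_domains",
           "run_contacts", "run_build", "run_fixtures"]


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    structures: list = field(default_factory=list)  # PDB paths
    annotation: str | None = None                   # TSV path (None: shipped table)
    contact_table: str | None = None                # TSV cutoff overrides
    chain_labels: list = field(default_factory=lambda: ["K1", "K10"])
    ca_cutoff: float = contacts.CA_CUTOFF
    psi_min: float = coil_geometry.PSI_MIN_DEG
    category_band: float = domain_geometry.CATEGORY_BAND
    hinge_convention: str = "interior"
    weighting: str = "per-model"
    output_dir: str = "ifdimer_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for p in self.structures:
            if not Path(p).exists():
                raise FileNotFoundError(f"structure file not found: {p}")
        for p in (self.annotation, self.contact_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config file not found: {p}")
        for name in ("ca_cutoff", "psi_min", "category_band"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hinge_convention not in ("interior", "paper"):
            raise ValueError("hinge_convention must be 'interior' or 'paper'")
        if self.weighting not in ("per-model", "per-frame"):
            raise ValueError("weighting must be 'per-model' or 'per-frame'")

    def load_annotation(self) -> SubdomainAnnotation:
        if self.annotation is None:
            return default_annotation()
        return load_annotation(self.annotation)

    def load_contact_table(self) -> contacts.ContactTypeTable:
        if self.contact_table is None:
            return contacts.DEFAULT_CONTACT_TABLE
        return contacts.ContactTypeTable.from_tsv(self.contact_table)

    def load_ensemble(self) -> Ensemble:
        if not self.structures:
            raise ValueError("no input structures configured")
        frames, model_ids, scopes = [], [], []
        for mid, path in enumerate(self.structures):
            ens = read_pdb(path, labels=self._labels_for(path))
            for fr in ens.frames:
                frames.append(fr)
                model_ids.append(mid)
                scopes.append("full")
        return Ensemble(frames, model_ids, scopes)

    def _labels_for(self, path):
        ens = read_pdb(path)
        if len(ens.frames[0].chains) == len(self.chain_labels):
            return self.chain_labels
        return None


@dataclass
class RunReport:
    outputs: dict = field(default_factory=dict)   # name -> path
    row_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def add(self, name: str, path, rows: int | None = None):
        self.outputs[name] = str(path)
        if rows is not None:
            self.row_counts[name] = rows

    def write(self, out_dir: Path, stage: str):
        path = Path(out_dir) / f"{stage}_report.yaml"
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path


def _prepare(config: RunConfig):
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_tsv(df: pd.DataFrame, path: Path, float_format="%.4f"):
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------------

def run_geometry(config: RunConfig) -> RunReport:
    """Coiled-coil profiles: per-residue R/Ψ/λ/handedness TSV, per-subdomain
    means and per-frame hinge angles."""
    out = _prepare(config)
    annotation = config.load_annotation()
    ensemble = config.load_ensemble()
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    report = RunReport()
    t0 = time.perf_counter()

    la, lb = ensemble.frames[0].labels[:2]
    for sub in COIL_SUBDOMAINS:
        if not (annotation.has(la, sub) and annotation.has(lb, sub)):
            raise ValueError(f"annotation is missing rod subdomain {sub}")

    profile_rows, mean_rows, hinge_rows = [], [], []
    for k, frame in enumerate(ensemble):
        axes = {}
        for sub in COIL_SUBDOMAINS:
            prof = coil_geometry.subdomain_profile(frame, annotation, sub,
                                                   psi_min=config.psi_min)
            resnums = prof.residue_numbers
            for i in prof.indices():
                profile_rows.append({
                    "frame": k, "subdomain": sub,
                    "res_" + la: resnums[la].get(i, ""),
                    "res_" + lb: resnums[lb].get(i, ""),
                    "radius_A": prof.radius.get(i, np.nan),
                    "psi_deg": prof.psi.get(i, np.nan),
                    "pitch_A": prof.pitch.get(i) if prof.pitch.get(i) is not None else np.nan,
                    "handedness": prof.handedness.get(i, ""),
                })
            sa, ea = annotation.interval(la, sub)
            sb, eb = annotation.interval(lb, sub)
            n_range = min(ea - sa, eb - sb) + 1
            axes[sub] = coil_geometry.compute_major_axis(
                prof.central_axis, sub, n_range=n_range)
            try:
                mean_pitch = prof.mean_pitch()
            except ValueError:
                mean_pitch = np.nan
            mean_rows.append({
                "frame": k, "subdomain": sub,
                "mean_radius_A": prof.mean_radius(),
                "mean_pitch_A": mean_pitch,
            })
        for u, v in (("1A", "1B"), ("1B", "2A"), ("2A", "2B")):
            if u in axes and v in axes:
                hinge_rows.append({
                    "frame": k, "pair": f"{u}/{v}",
                    "hinge_deg": coil_geometry.compute_hinge_angle(
                        axes[u], axes[v], convention=config.hinge_convention),
                    "convention": config.hinge_convention,
                })

    prof_df = pd.DataFrame(profile_rows)
    mean_df = pd.DataFrame(mean_rows)
    hinge_df = pd.DataFrame(hinge_rows)
    _write_tsv(prof_df, out / "profile.tsv")
    _write_tsv(mean_df, out / "subdomain_means.tsv")
    _write_tsv(hinge_df, out / "hinge_angles.tsv")
    report.add("profile", out / "profile.tsv", len(prof_df))
    report.add("subdomain_means", out / "subdomain_means.tsv", len(mean_df))
    report.add("hinge_angles", out / "hinge_angles.tsv", len(hinge_df))
    report.timings["geometry_s"] = round(time.perf_counter() - t0, 3)
    report.write(out, "geometry")
    return report


def run_domains(config: RunConfig) -> RunReport:
    """Head/tail placement and shape: per-frame (d, θr, category, Rg,
    end-to-end, extents) plus occurrence histograms."""
    out = _prepare(config)
    annotation = config.load_annotation()
    ensemble = config.load_ensemble()
    report = RunReport()
    t0 = time.perf_counter()

    la, lb = ensemble.frames[0].labels[:2]
    if not any(annotation.has(c, s) for c in (la, lb) for s in HEAD_SUBDOMAINS + TAIL_SUBDOMAINS):
        raise ValueError("annotation has no head or tail subdomains")

    rows = []
    positions = {"head": [], "tail": []}
    for k, frame in enumerate(ensemble):
        for domain, globule_sub, anchor_end in (
            ("head", "V1", "N-term-1A"),
            ("tail", "V2", "C-term-2B"),
        ):
            chains_with = [c for c in (la, lb) if annotation.has(c, globule_sub)]
            if not chains_with:
                continue
            try:
                anchor_frame = domain_geometry.rod_anchor_frame(
                    frame, annotation, anchor_end)
            except (KeyError, ValueError) as exc:
                report.warnings.append(
                    f"frame {k}: no {anchor_end} anchor ({exc}); {domain} rows skipped")
                continue
            for label in chains_with:
                s, e = annotation.interval(label, globule_sub)
                chain = frame.chain(label)
                sub = chain.subset(s, e)
                if len(sub) == 0:
                    report.warnings.append(
                        f"frame {k}: chain {label} has no residues in "
                        f"{globule_sub} {s}-{e} (truncated model?)")
                    continue
                pos = domain_geometry.globule_position(
                    sub.ca_coords, anchor_frame, label, globule_sub)
                cat = domain_geometry.classify_category(pos, config.category_band)
                metrics = domain_geometry.shape_metrics(
                    chain, domain, anchor_frame.anchor, s, e)
                ext = metrics.principal_extents
                rows.append({
                    "frame": k, "chain": label, "subdomain": globule_sub,
                    "d_A": pos.d,
                    "theta_r_deg": pos.theta_r if pos.theta_r is not None else np.nan,
                    "category": cat,
                    "rg_A": metrics.rg,
                    "end_to_end_A": metrics.end_to_end,
                    "extent1_A": ext[0], "extent2_A": ext[1], "extent3_A": ext[2],
                    "extent1_nm": ext[0] / 10.0, "extent2_nm": ext[1] / 10.0,
                    "extent3_nm": ext[2] / 10.0,
                })
                positions[domain].append(pos)

    pos_df = pd.DataFrame(rows)
    _write_tsv(pos_df, out / "positions.tsv")
    report.add("positions", out / "positions.tsv", len(pos_df))
    for domain, plist in positions.items():
        if plist:
            hist = domain_geometry.position_histogram(plist)
            _write_tsv(hist, out / f"{domain}_histogram.tsv")
            report.add(f"{domain}_histogram", out / f"{domain}_histogram.tsv", len(hist))
    report.timings["domains_s"] = round(time.perf_counter() - t0, 3)
    report.write(out, "domains")
    return report


def run_contacts(config: RunConfig) -> RunReport:
    """Cα contact probabilities per chain class, typed side-chain census
    and hydrogen-bond counts."""
    out = _prepare(config)
    table = config.load_contact_table()
    ensemble = config.load_ensemble()
    report = RunReport()
    t0 = time.perf_counter()

    maps = [contacts.ca_contact_map(fr, cutoff=config.ca_cutoff)
            for fr in ensemble]
    matrix = contacts.aggregate_contact_probability(
        maps, ensemble, weighting=config.weighting)
    mat_df = matrix.to_dataframe()
    _write_tsv(mat_df, out / "contact_probability.tsv")
    report.add("contact_probability", out / "contact_probability.tsv", len(mat_df))
    if not mat_df.empty:
        for cls, group in mat_df.groupby("class"):
            fname = f"contact_probability_{cls.replace('-', '_')}.tsv"
            _write_tsv(group, out / fname)
            report.add(f"contact_probability[{cls}]", out / fname, len(group))

    census = contacts.summarize_contacts(ensemble, table)
    _write_tsv(census.pair_probabilities, out / "sidechain_census.tsv")
    report.add("sidechain_census", out / "sidechain_census.tsv",
               len(census.pair_probabilities))
    totals = census.mean_counts.reset_index()
    _write_tsv(totals, out / "sidechain_totals.tsv")
    report.add("sidechain_totals", out / "sidechain_totals.tsv", len(totals))

    hb_rows = []
    for k, frame in enumerate(ensemble):
        counts = contacts.count_hbonds(frame)
        counts["frame"] = k
        hb_rows.append(counts)
    hb_df = pd.DataFrame(hb_rows)
    _write_tsv(hb_df, out / "hbond_counts.tsv")
    report.add("hbond_counts", out / "hbond_counts.tsv", len(hb_df))
    report.timings["contacts_s"] = round(time.perf_counter() - t0, 3)
    report.write(out, "contacts")
    return report


def run_build(config: RunConfig) -> RunReport:
    """The 25-model configuration manifest, hairpin-turn PDB fragments and
    the truncation restraint block."""
    out = _prepare(config)
    report = RunReport()
    t0 = time.perf_counter()

    configs = model_builder.enumerate_models()
    rows = []
    for i, cfg in enumerate(configs):
        row = {
            "model": i, "orientation": cfg.orientation,
            "n_shift": cfg.n_shift, "scope": cfg.scope,
        }
        for chain, (s, e) in cfg.head_turn_window.items():
            row[f"head_turn_{chain}"] = f"{s}-{e}"
        if cfg.tail_turn_window:
            for chain, (s, e) in cfg.tail_turn_window.items():
                row[f"tail_turn_{chain}"] = f"{s}-{e}"
        rows.append(row)
    manifest = pd.DataFrame(rows)
    _write_tsv(manifest, out / "model_manifest.tsv")
    report.add("model_manifest", out / "model_manifest.tsv", len(manifest))

    spec = model_builder.DihedralSpec.uniform(
        model_builder.HAIRPIN_LENGTH, model_builder.HAIRPIN_PHI,
        model_builder.HAIRPIN_PSI, model_builder.HAIRPIN_OMEGA)
    import warnings as _warnings
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        turn = model_builder.chain_from_dihedrals("G" * model_builder.HAIRPIN_LENGTH,
                                                  spec, label="T")
    report.warnings.extend(str(w.message) for w in caught)
    write_pdb(turn_structure(turn), out / "hairpin_turn.pdb")
    report.add("hairpin_turn", out / "hairpin_turn.pdb")

    restraint = model_builder.truncation_spec()
    (out / "restraint.txt").write_text(restraint.to_text())
    report.add("restraint", out / "restraint.txt")
    report.timings["build_s"] = round(time.perf_counter() - t0, 3)
    report.write(out, "build")
    return report


def turn_structure(chain):
    from .structure_io import DimerStructure
    return DimerStructure([chain])


def run_fixtures(output_dir, seed: int = 0) -> RunReport:
    """Materialize the standard synthetic test set as PDB files."""
    from . import synthetic_data as syn
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    coil = syn.generate_crick_coil(syn.CrickParams(
        r0=5.0, superhelical_pitch=170.0, handedness="left", n_residues=100))
    write_pdb(coil, out / "crick_coil.pdb")
    report.add("crick_coil", out / "crick_coil.pdb")
    helix = syn.generate_alpha_helix(50)
    write_pdb(turn_structure(helix), out / "alpha_helix.pdb")
    report.add("alpha_helix", out / "alpha_helix.pdb")
    globule = syn.generate_globular_chain(100, 25.0, seed=seed)
    write_pdb(turn_structure(globule), out / "globule.pdb")
    report.add("globule", out / "globule.pdb")
    jitter = syn.perturb_ensemble(coil, 5, syn.NoiseSpec(sigma=0.5, seed=seed))
    write_pdb(jitter, out / "jittered_ensemble.pdb")
    report.add("jittered_ensemble", out / "jittered_ensemble.pdb")
    report.write(out, "fixtures")
    return report
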