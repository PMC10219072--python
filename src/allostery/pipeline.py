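"""End-to-end WT-vs-perturbed comparison pipeline.

Orchestrates: synthetic reference -> elastic-network models (wild type and
contact-perturbed) -> Gaussian ensembles -> structural descriptors ->
essential dynamics (DCCM, PCA, free-energy landscape) -> perturbation
response scanning -> LMI residue network and normalized BC difference.
Every stage is seeded from the run configuration and all artifacts are
written as labelled TSV with a manifest, so reruns with the same config
are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import essential, geometry, io, network, synth
from .enm import build_anm_from_contacts, contact_pairs, prs_scan, prs_difference
from .model import Domain

logger = logging.getLogger("allostery")

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline", "summarize_series", "format_mean_sd"]


@dataclass
class RunConfig:
    """All tunable parameters of a comparison run, with field defaults.

    Distance/angle defaults follow the analysis conventions this package
    implements: 3.5 A / 30 deg hydrogen bonds, 12 A ANM cutoff, 20 slow
    modes for PRS, 15 A porcupine arrow cutoff, +/-0.1 BC-difference
    flags, bin-500 moving averages.
    """

    seed: int = 1
    out_dir: str | None = None
    n_frames: int = 3000
    kT: float = 1.0
    anm_cutoff: float = 12.0
    n_modes: int = 20
    hbond_d_max: float = 3.5
    hbond_angle_max: float = 30.0
    salt_bridge_d_max: float = 4.0
    fel_bins: int = 50
    fel_basin_depth: float = 1.0  # kT; minima deeper than this count as basins
    porcupine_min_length: float = 15.0
    porcupine_scale: float = 1.0
    bc_flag_threshold: float = 0.1
    moving_average_bin: int = 500
    edge_cutoff: float = 10.0
    edge_persistence: float = 0.75
    write_ensembles: bool = False
    perturbation: synth.PerturbationSpec = field(default_factory=synth.phospho_spec)
    synth_spec: synth.SyntheticSpec | None = None

    def to_flat(self) -> dict:
        d = asdict(self)
        d["perturbation.removed"] = ";".join(
            f"{a}-{b}" for a, b in self.perturbation.removed_contacts
        )
        d["perturbation.added"] = ";".join(
            f"{a}-{b}" for a, b in self.perturbation.added_contacts
        )
        d.pop("perturbation")
        d.pop("synth_spec")
        d.pop("out_dir")  # path-bearing, not a scientific parameter
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = io.read_config(path)
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name in raw and f_.name not in ("perturbation", "synth_spec"):
                cast = type(getattr(cls(), f_.name)) if getattr(cls(), f_.name) is not None else str
                val = raw[f_.name]
                kwargs[f_.name] = cast(val) if cast is not bool else val.lower() in ("1", "true", "yes")
        pert = synth.PerturbationSpec(
            removed_contacts=_parse_pairs(raw.get("perturbation.removed", "44-335")),
            added_contacts=_parse_pairs(raw.get("perturbation.added", "44-149")),
        )
        kwargs["perturbation"] = pert
        return cls(**kwargs)


def _parse_pairs(text):
    pairs = []
    for tok in text.split(";"):
        tok = tok.strip()
        if tok:
            a, b = tok.split("-")
            pairs.append((int(a), int(b)))
    return pairs


@dataclass
class ComparisonReport:
    """Paired summaries and difference artifacts of a WT-vs-perturbed run."""

    config: RunConfig
    summaries: dict
    flags: list
    delta_bc: np.ndarray
    dccm_difference: np.ndarray
    prs_ranked: list
    basins: dict
    manifest: list

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries,
            "flags": self.flags,
            "n_bc_flags": len(self.flags),
            "prs_top_changes": self.prs_ranked[:10],
            "basins": self.basins,
            "manifest": self.manifest,
        }


def summarize_series(series) -> tuple[float, float]:
    """Arithmetic mean and population (divisor n) standard deviation."""
    x = np.asarray(
        series.values if isinstance(series, geometry.DescriptorSeries) else series,
        dtype=float,
    )
    if x.size == 0:
        raise ValueError("empty series")
    return float(x.mean()), float(x.std(ddof=0))


def format_mean_sd(series) -> str:
    """Format as ``mean (sd)``, the convention used in comparison tables."""
    m, s = summarize_series(series)
    return f"{m:.2f} ({s:.2f})"


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Run the full comparison and return a :class:`ComparisonReport`.

    Deterministic for a given config: the wild-type ensemble uses
    ``seed`` and the perturbed ensemble ``seed + 1``. When ``out_dir``
    is set, all series/matrices/tables are written there with a manifest
    recording every parameter.
    """
    cfg = config
    manifest: list = []
    out = cfg.out_dir
    if out:
        os.makedirs(out, exist_ok=True)
        fh = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
        fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(fh)
    try:
        return _run(cfg, manifest, out)
    finally:
        if out:
            logger.removeHandler(fh)
            fh.close()


def _run(cfg: RunConfig, manifest, out) -> ComparisonReport:
    def save_matrix(name, matrix, labels=None):
        if out:
            path = os.path.join(out, name)
            io.write_matrix(matrix, path, labels=labels)
            manifest.append(name)

    def save_table(name, records, columns=None):
        if out:
            io.write_table(records, os.path.join(out, name), columns=columns)
            manifest.append(name)

    # the reference complex is the fixed study system (generator defaults);
    # the run seed drives the stochastic ensembles sampled around it
    logger.info("stage synth: building reference (run seed=%d)", cfg.seed)
    spec = cfg.synth_spec or synth.SyntheticSpec()
    try:
        ref = synth.make_reference(spec)
    except Exception as exc:
        raise RuntimeError(f"stage synth failed on spec seed={spec.seed}: {exc}") from exc
    labels = ref.labels
    if out:
        io.write_reference_pdb(ref, os.path.join(out, "reference.pdb"))
        manifest.append("reference.pdb")

    logger.info(
        "stage anm: cutoff=%.1f A, perturbation removes %s adds %s",
        cfg.anm_cutoff,
        cfg.perturbation.removed_contacts,
        cfg.perturbation.added_contacts,
    )
    coords = ref.reference_coords
    wt_contacts = contact_pairs(coords, cfg.anm_cutoff)
    mut_contacts = synth.apply_perturbation(wt_contacts, cfg.perturbation, ref)
    anms = {
        "wt": build_anm_from_contacts(ref, coords, wt_contacts, cutoff=cfg.anm_cutoff),
        "perturbed": build_anm_from_contacts(ref, coords, mut_contacts, cutoff=cfg.anm_cutoff),
    }

    logger.info("stage sample: %d frames per system, kT=%.2f", cfg.n_frames, cfg.kT)
    ensembles = {
        "wt": synth.sample_anm_ensemble(anms["wt"], cfg.n_frames, cfg.kT, seed=cfg.seed),
        "perturbed": synth.sample_anm_ensemble(
            anms["perturbed"], cfg.n_frames, cfg.kT, seed=cfg.seed + 1
        ),
    }
    if cfg.write_ensembles and out:
        for name, ens in ensembles.items():
            io.write_frame_table(ens, os.path.join(out, f"{name}_ensemble.tsv"))
            manifest.append(f"{name}_ensemble.tsv")

    logger.info("stage descript: RMSD/Rg/RMSF/domain distances")
    summaries: dict = {}
    rmsf_by_system = {}
    covs = {}
    dccms = {}
    for name, ens in ensembles.items():
        rs = geometry.rmsd_series(ens, reference=coords)
        rg = geometry.rg_series(ens)
        fl = geometry.rmsf(ens, align_first=True)
        dist = geometry.distance_series(ens, "LYASE", "C", mode="centroid")
        summaries[name] = {
            "rmsd": format_mean_sd(rs),
            "rg": format_mean_sd(rg),
            "lyase_C_distance": format_mean_sd(dist),
            "mean_rmsf": float(fl.mean()),
        }
        rmsf_by_system[name] = fl
        save_table(
            f"{name}_series.tsv",
            {
                "frame": np.arange(ens.n_frames),
                "rmsd": rs.values,
                "rg": rg.values,
                "lyase_C_distance": dist.values,
                "lyase_C_distance_smooth": geometry.moving_average(
                    dist.values, min(cfg.moving_average_bin, ens.n_frames)
                ),
            },
        )
        logger.info("stage ed (%s): covariance, DCCM, PCA, FEL", name)
        cov = essential.covariance(ens, align=False)  # samples carry no rigid motion
        covs[name] = cov
        dccms[name] = essential.dccm(cov)
        save_matrix(f"{name}_dccm.tsv", dccms[name].matrix, labels=labels)
        save_table(f"{name}_rmsf.tsv", {"label": labels, "rmsf": fl})

    for name, fl in rmsf_by_system.items():
        lyase = ref.domain_indices(Domain.LYASE)
        summaries[name]["lyase_rmsf"] = float(fl[lyase].mean())

    pcs = {}
    basins_out = {}
    for name, cov in covs.items():
        modes = essential.pca(cov, n_components=cfg.n_modes)
        summaries[name]["pc1_variance_fraction"] = modes[0]["variance_fraction"]
        summaries[name][f"first_{cfg.n_modes}_variance_fraction"] = modes[-1][
            "cumulative_fraction"
        ]
        p1 = essential.project(ensembles[name], cov, 0)
        p2 = essential.project(ensembles[name], cov, 1)
        p1.cosine_content = essential.cosine_content(p1)
        summaries[name]["pc1_cosine_content"] = p1.cosine_content
        fel = essential.free_energy_landscape(p1.values, p2.values, cfg.fel_bins, cfg.kT)
        basins = essential.detect_basins(fel, depth_threshold=cfg.fel_basin_depth * cfg.kT)
        basins_out[name] = [
            {k: v for k, v in b.items() if k != "bin"} for b in basins[:5]
        ]
        summaries[name]["n_basins"] = len(basins)
        pcs[name] = (p1, p2)
        if out:
            io.write_matrix(
                fel.free_energy,
                os.path.join(out, f"{name}_fel.tsv"),
                row_labels=np.round(0.5 * (fel.x_edges[:-1] + fel.x_edges[1:]), 4),
                col_labels=np.round(0.5 * (fel.y_edges[:-1] + fel.y_edges[1:]), 4),
            )
            manifest.append(f"{name}_fel.tsv")
        arrows = essential.porcupine_vectors(
            cov, 0, scale=cfg.porcupine_scale, min_length=0.0
        )
        save_table(
            f"{name}_porcupine_pc1.tsv",
            [
                {
                    "label": labels[a["site_index"]],
                    "x": a["anchor"][0],
                    "y": a["anchor"][1],
                    "z": a["anchor"][2],
                    "dx": a["vector"][0],
                    "dy": a["vector"][1],
                    "dz": a["vector"][2],
                    "length": a["length"],
                }
                for a in arrows
            ],
        )

    dccm_diff = essential.map_difference(dccms["perturbed"], dccms["wt"])
    save_matrix("dccm_difference.tsv", dccm_diff, labels=labels)

    logger.info("stage prs: %d modes", cfg.n_modes)
    prs_maps = {name: prs_scan(anm, cfg.n_modes) for name, anm in anms.items()}
    prs_diff, prs_ranked = prs_difference(prs_maps["perturbed"], prs_maps["wt"])
    for rec in prs_ranked:
        rec["label"] = labels[rec["site_index"]]
    save_matrix("prs_difference.tsv", prs_diff, labels=labels)
    for name, pm in prs_maps.items():
        save_table(
            f"{name}_prs_profiles.tsv",
            {
                "label": labels,
                "domain": [
                    s.domain.value if s.domain else "LINKER" for s in ref.sites
                ],
                "effectiveness": pm.effectiveness,
                "sensitivity": pm.sensitivity,
            },
        )

    logger.info(
        "stage net: LMI network on system contact sets, flag threshold %.2f",
        cfg.bc_flag_threshold,
    )
    nets = {}
    for name, contacts in (("wt", wt_contacts), ("perturbed", mut_contacts)):
        lmi = network.lmi_from_covariance(covs[name].gamma)
        nets[name] = network.build_network(
            lmi.generalized_correlation, contacts, site_model=ref
        )
    delta_bc, flags = network.bc_difference(
        nets["perturbed"], nets["wt"], cfg.bc_flag_threshold
    )
    save_table(
        "bc_difference.tsv",
        {
            "label": labels,
            "domain": [s.domain.value if s.domain else "LINKER" for s in ref.sites],
            "bc_wt": [nets["wt"].bc[i] for i in range(ref.n_sites)],
            "bc_perturbed": [nets["perturbed"].bc[i] for i in range(ref.n_sites)],
            "delta_bc": delta_bc,
            "flagged": np.abs(delta_bc) > cfg.bc_flag_threshold,
        },
    )

    report = ComparisonReport(
        config=cfg,
        summaries=summaries,
        flags=flags,
        delta_bc=delta_bc,
        dccm_difference=dccm_diff,
        prs_ranked=prs_ranked,
        basins=basins_out,
        manifest=manifest,
    )
    if out:
        with open(os.path.join(out, "report.json"), "w") as f:
            json.dump(report.to_dict(), f, indent=2, default=_json_default)
        with open(os.path.join(out, "manifest.json"), "w") as f:
            json.dump({"parameters": cfg.to_flat(), "artifacts": manifest}, f, indent=2)
        manifest.extend(["report.json", "manifest.json"])
    logger.info("pipeline complete: %d BC flags", len(flags))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
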