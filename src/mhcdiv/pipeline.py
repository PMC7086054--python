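"""End-to-end orchestration: supertypes -> associations -> null simulation
-> diversity -> differentiation, with a single config and deterministic seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_table, significant_pairs
from .data import (
    Dataset,
    incidence_matrix,
    read_allele_fasta,
    read_coords,
    read_genotype_table,
    write_allele_fasta,
    write_coords,
    write_genotype_table,
)
from .differentiation import (
    differentiation_matrix,
    geographic_distance,
    mantel,
    partial_mantel,
)
from .diversity import diversity_table
from .nullsim import (
    compare_supertype_means,
    incidence_spectrum,
    simulate_linked,
    simulate_unlinked,
)
from .simulate import make_msat_panel, make_study_like_dataset
from .supertypes import fit_supertypes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full-run configuration; every seed is explicit, no wall-clock seeding."""

    out_dir: str = "mhcdiv_run"
    seed: int = 0
    # inputs: either synthetic (default) or file paths
    synthetic: bool = True
    allele_fasta: str | None = None
    genotype_table: str | None = None
    coords_file: str | None = None
    frame_offset: int = 0
    pss_positions: list[int] = field(default_factory=lambda: [5, 12, 23, 37, 51])
    k_min: int = 1
    k_max: int = 15
    n_starts: int = 20
    bic_drop_threshold: float = 0.01
    k_override: int | None = None
    groups: dict[str, list[str]] | None = None
    alpha: float = 0.05
    n_perm_assoc: int = 99_999
    n_perm_rho: int = 999
    n_perm_mantel: int = 719
    ensemble_size: int = 50_000
    ks_resamples: int = 100_000
    linkage_mode: str = "complete"
    assembly: str = "bernoulli"
    rarefaction_g: int | None = None
    simulate_msat: bool = True
    coords_lonlat: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def echo(self, out: Path) -> None:
        out.joinpath("config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _load_dataset(cfg: RunConfig, out: Path):
    if cfg.synthetic:
        dataset, truth, coords = make_study_like_dataset(seed=cfg.seed)
        truth.to_json(out / "synthetic_truth.json")
        write_allele_fasta(dataset.catalog, out / "alleles.fasta")
        write_genotype_table(dataset, out / "genotypes.tsv")
        write_coords(coords, out / "coords.tsv")
        return dataset
    if not cfg.allele_fasta or not cfg.genotype_table:
        raise ValueError("non-synthetic run requires allele_fasta and genotype_table")
    catalog = read_allele_fasta(cfg.allele_fasta, frame_offset=cfg.frame_offset)
    coords = read_coords(cfg.coords_file) if cfg.coords_file else None
    return read_genotype_table(cfg.genotype_table, catalog, coords=coords)


def _disjoint_pairs(results):
    """Greedy disjoint subset of significant pairs, in ascending-p order."""
    used: set[str] = set()
    chosen = []
    for r in results:
        if not r.significant:
            continue
        a, b = r.pair
        if a in used or b in used:
            logger.warning("dropping overlapping linked pair (%s, %s)", a, b)
            continue
        used |= {a, b}
        chosen.append((a, b))
    return chosen


def run_all(cfg: RunConfig) -> dict:
    """Run every stage, writing a deterministic report bundle to cfg.out_dir.

    Any stage failure writes a FAILED marker naming the stage and re-raises;
    outputs of completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.echo(out)
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in ("supertypes", "assoc", "nullsim", "rho", "mantel", "msat")
    }
    report: dict = {"version": __version__, "seed": cfg.seed, "stage_seeds": stage_seeds}
    stage = "load"
    try:
        dataset = _load_dataset(cfg, out)
        report["n_individuals"] = len(dataset.genotypes)
        report["n_alleles"] = len(dataset.catalog)
        report["sites"] = list(dataset.sites)

        stage = "supertypes"
        model = fit_supertypes(
            dataset.catalog,
            cfg.pss_positions,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_starts=cfg.n_starts,
            seed=stage_seeds["supertypes"],
            drop_threshold=cfg.bic_drop_threshold,
            k_override=cfg.k_override,
        )
        pd.DataFrame(
            sorted(model.assignment.items()), columns=["allele_id", "supertype"]
        ).to_csv(out / "supertype_map.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(model.bic_curve.items()), columns=["k", "BIC"]
        ).to_csv(out / "bic_curve.tsv", sep="\t", index=False)
        report["supertypes_k"] = model.k

        stage = "assoc+nullsim"
        groups = cfg.groups or {"all": list(dataset.sites)}
        report["groups"] = {}
        for name, sites in groups.items():
            assoc = significant_pairs(
                dataset,
                alpha=cfg.alpha,
                n_perm=cfg.n_perm_assoc,
                seed=stage_seeds["assoc"],
                site_filter=sites,
            )
            association_table(assoc).to_csv(
                out / f"associations_{name}.tsv", sep="\t", index=False
            )
            linked = _disjoint_pairs(assoc)
            spectrum = incidence_spectrum(dataset, sites)
            observed = dataset.site_genotypes(sites)
            unlinked = simulate_unlinked(
                spectrum, cfg.ensemble_size, seed=stage_seeds["nullsim"],
                assembly=cfg.assembly,
            )
            rep_u = compare_supertype_means(
                observed, model, unlinked,
                n_resamples=cfg.ks_resamples, seed=stage_seeds["nullsim"],
            )
            group_report = {
                "n_significant_pairs": len([r for r in assoc if r.significant]),
                "linked_pairs_used": linked,
                "unlinked": rep_u,
            }
            if linked:
                linked_ens = simulate_linked(
                    spectrum, linked, cfg.ensemble_size,
                    seed=stage_seeds["nullsim"] + 1, linkage_mode=cfg.linkage_mode,
                )
                group_report["linked"] = compare_supertype_means(
                    observed, model, linked_ens,
                    n_resamples=cfg.ks_resamples, seed=stage_seeds["nullsim"] + 1,
                )
            report["groups"][name] = group_report
            (out / f"nullsim_{name}.json").write_text(
                json.dumps(group_report, indent=2, default=str)
            )

        stage = "diversity"
        div = diversity_table(
            dataset, model=model, g=cfg.rarefaction_g,
            pss_positions=cfg.pss_positions, groups=cfg.groups,
        )
        div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.4f")
        report["diversity_rows"] = len(div)

        stage = "differentiation"
        diff = differentiation_matrix(
            dataset, n_perm=cfg.n_perm_rho, seed=stage_seeds["rho"], marker_label="MHC"
        )
        diff.rho_transformed.to_csv(out / "rho_mhc.tsv", sep="\t")
        diff.p_values.to_csv(out / "rho_mhc_p.tsv", sep="\t")
        report["global_rho_mhc"] = diff.global_rho
        report["global_rho_transformed_mhc"] = diff.global_transformed

        stage = "mantel"
        if cfg.simulate_msat and cfg.synthetic:
            panel, _ = make_msat_panel(
                n_sites=len(dataset.sites),
                individuals_per_site=[dataset.n_individuals(s) for s in dataset.sites],
                divergence=0.25,
                seed=stage_seeds["msat"],
                site_ids=list(dataset.sites),
            )
            mdiff = differentiation_matrix(
                panel, n_perm=cfg.n_perm_rho, seed=stage_seeds["rho"] + 1,
                marker_label="msat",
            )
            mdiff.rho_transformed.to_csv(out / "rho_msat.tsv", sep="\t")
            report["global_rho_transformed_msat"] = mdiff.global_transformed
        else:
            mdiff = None
        if dataset.coords:
            geo = geographic_distance(
                dataset.coords, sites=list(dataset.sites), lonlat=cfg.coords_lonlat
            )
            r, p = mantel(
                diff.rho_transformed, geo, n_perm=cfg.n_perm_mantel,
                seed=stage_seeds["mantel"],
            )
            mantel_report = {"mhc_vs_distance": {"r": r, "p": p}}
            if mdiff is not None:
                r2, p2 = mantel(
                    mdiff.rho_transformed, geo, n_perm=cfg.n_perm_mantel,
                    seed=stage_seeds["mantel"] + 1,
                )
                r3, p3 = partial_mantel(
                    diff.rho_transformed, geo, mdiff.rho_transformed,
                    n_perm=cfg.n_perm_mantel, seed=stage_seeds["mantel"] + 2,
                )
                r4, p4 = partial_mantel(
                    diff.rho_transformed, mdiff.rho_transformed, geo,
                    n_perm=cfg.n_perm_mantel, seed=stage_seeds["mantel"] + 3,
                )
                mantel_report.update(
                    {
                        "msat_vs_distance": {"r": r2, "p": p2},
                        "mhc_vs_distance_given_msat": {"r": r3, "p": p3},
                        "mhc_vs_msat_given_distance": {"r": r4, "p": p4},
                    }
                )
            (out / "mantel.json").write_text(json.dumps(mantel_report, indent=2))
            report["mantel"] = mantel_report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "run_log.json").write_text(json.dumps(report, indent=2, default=str))
    return report
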