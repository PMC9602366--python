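"""One-command reproduction of the full analysis from FASTA + popmap.

``run_all`` chains every stage — masking, haplotype collapsing, diversity,
pairwise Phi_ST / gene flow, AMOVA, neutrality tests, mismatch-expansion
fitting with dating, and the median-joining network — and writes one
tabular artifact per stage plus a JSON manifest holding every parameter
needed to reproduce any reported number.

Report rounding: pi to 4 decimals, Phi_ST and Nm to 3, times to whole
years; the manifest and JSON outputs keep full precision.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, demography, differentiation, diversity, network
from . import neutrality as neut
from .seqio import (
    Alignment,
    PopulationMap,
    collapse_haplotypes,
    mask_sites,
    read_fasta,
    read_popmap,
)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    fasta: Path
    popmap: Path
    out_dir: Path
    seed: int
    groupings: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_perm: int = 10_000
    n_sims: int = 1000
    mismatch_bounds: tuple = demography.DEFAULT_BOUNDS
    rate_per_site_per_year: float = 3.6e-8
    epsilon: int = 0
    mask_policy: str = "complete_deletion"
    quiet: bool = False


def _log(cfg: RunConfig, msg: str, t0: float) -> None:
    if not cfg.quiet:
        print(f"[mtpopgen +{time.perf_counter() - t0:6.1f}s] {msg}",
              file=sys.stderr)


def _header(cfg: RunConfig) -> str:
    return f"# mtpopgen {__version__} seed={cfg.seed}\n"


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mtpopgen",
        "version": __version__,
        "python": sys.version.split()[0],
        "parameters": {
            "fasta": str(cfg.fasta),
            "popmap": str(cfg.popmap),
            "seed": cfg.seed,
            "groupings": {k: list(v) for k, v in cfg.groupings.items()},
            "n_perm": cfg.n_perm,
            "n_sims": cfg.n_sims,
            "mismatch_bounds": [list(b) for b in cfg.mismatch_bounds],
            "rate_per_site_per_year": cfg.rate_per_site_per_year,
            "epsilon": cfg.epsilon,
            "mask_policy": cfg.mask_policy,
        },
        "stages": {},
    }
    stage = "load"
    try:
        aln = read_fasta(cfg.fasta)
        pm = read_popmap(cfg.popmap)
        for name, members in cfg.groupings.items():
            pm = pm.with_grouping(name, members)
        pm.validate_against(aln)
        masked, site_map = mask_sites(aln, cfg.mask_policy)
        ht = collapse_haplotypes(masked, pm)
        manifest["stages"]["load"] = {
            "n_samples": masked.n,
            "sites_analyzed": masked.length,
            "sites_input": aln.length,
            "n_haplotypes": ht.n_haplotypes,
        }
        _log(cfg, f"loaded {masked.n} seqs, {masked.length} analyzed sites, "
                  f"{ht.n_haplotypes} haplotypes", t0)

        pops = list(pm.populations)
        groups = list(cfg.groupings)
        units = pops + groups

        stage = "diversity"
        div = {u: diversity.population_diversity(masked, pm, u) for u in units}
        _write_diversity(cfg, out / "diversity.tsv", div, units)
        manifest["stages"]["diversity"] = {
            u: {"n": d.n, "nh": d.nh, "h": d.h, "se_h": d.se_h,
                "pi": d.pi, "se_pi": d.se_pi, "S": d.S, "k_hat": d.k_hat,
                "ti": d.ti, "tv": d.tv}
            for u, d in div.items()
        }
        _log(cfg, "diversity table written", t0)

        stage = "differentiation"
        dm = differentiation.pairwise_differences(masked)
        fm = differentiation.fst_matrix(
            dm, pm, pops, n_perm=cfg.n_perm, seed=cfg.seed
        )
        overall = differentiation.amova_two_level(
            dm, pm, n_perm=cfg.n_perm, seed=cfg.seed, populations=pops
        )
        group_results = {}
        if groups:
            # grouped units plus any ungrouped base populations
            grouped_base = {m for g in cfg.groupings.values() for m in g}
            units2 = groups + [p for p in pops if p not in grouped_base]
            if len(units2) >= 2:
                group_results["amova"] = differentiation.amova_two_level(
                    dm, pm, n_perm=cfg.n_perm, seed=cfg.seed,
                    populations=units2,
                )
                group_results["units"] = units2
        _write_fst(cfg, out / "fst_nm.tsv", fm, overall, group_results)
        manifest["stages"]["differentiation"] = {
            "overall_fst": overall.fst,
            "overall_p": overall.p_value,
            "pairwise": {
                f"{fm.populations[i]}|{fm.populations[j]}": {
                    "fst": float(fm.fst[i, j]), "p": float(fm.p[i, j]),
                }
                for i in range(len(fm.populations))
                for j in range(i + 1, len(fm.populations))
            },
        }
        amova_res = group_results.get("amova", overall)
        _write_amova(cfg, out / "amova.tsv", amova_res)
        manifest["stages"]["amova"] = {
            "fst": amova_res.fst,
            "p_value": amova_res.p_value,
            "pct_among": amova_res.pct_among,
            "pct_within": amova_res.pct_within,
            "sigma2_a": amova_res.sigma2_a,
            "sigma2_w": amova_res.sigma2_w,
        }
        _log(cfg, f"differentiation done (overall Phi_ST={overall.fst:.3f})",
             t0)

        stage = "neutrality+mismatch"
        rows = []
        for u in units:
            sub = masked.subset(pm.members(u))
            d = div[u]
            try:
                td = neut.tajimas_d(sub, n_sims=cfg.n_sims, seed=cfg.seed)
                D, d_p = td.D, td.p_value
            except neut.UndefinedStatisticError:
                D = d_p = None
            try:
                ff = neut.fus_fs(sub, n_sims=cfg.n_sims, seed=cfg.seed)
                fs, fs_p = ff.fs, ff.p_value
            except neut.UndefinedStatisticError:
                fs = fs_p = None
            mm = demography.observed_mismatch(dm, pm.members(u), u)
            fit = demography.fit_expansion(
                mm, bounds=cfg.mismatch_bounds, seed=cfg.seed
            )
            et = demography.expansion_time(
                fit.tau, masked.length, cfg.rate_per_site_per_year
            )
            rows.append((u, d, D, d_p, fs, fs_p, fit, et))
        _write_neutrality(cfg, out / "neutrality_mismatch.tsv", rows)
        manifest["stages"]["neutrality_mismatch"] = {
            u: {
                "D": D, "D_p": d_p, "Fs": fs, "Fs_p": fs_p,
                "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
                "ssd": fit.ssd, "t_years": et.t_years,
            }
            for (u, d, D, d_p, fs, fs_p, fit, et) in rows
        }
        _log(cfg, "neutrality and mismatch tables written", t0)

        stage = "network"
        net = network.median_joining(ht, epsilon=cfg.epsilon)
        network.export_network(net, out / "network.tsv", "edge_tsv")
        network.export_network(net, out / "network.graphml", "graphml")
        manifest["stages"]["network"] = {
            "n_observed": len(net.observed),
            "n_median_vectors": len(net.median_vectors),
            "n_edges": len(net.edges),
        }
        _log(cfg, "network exported", t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    _log(cfg, "manifest written", t0)
    return manifest


def _fmt(x, nd):
    return "NA" if x is None else f"{x:.{nd}f}"


def _write_diversity(cfg, path, div, units) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("population\tn\tnh\th\tse_h\tpi\tse_pi\tS\tk_hat\tti\ttv\n")
        for u in units:
            d = div[u]
            fh.write(
                f"{u}\t{d.n}\t{d.nh}\t{d.h:.4f}\t{d.se_h:.4f}\t"
                f"{d.pi:.4f}\t{d.se_pi:.4f}\t{d.S}\t{d.k_hat:.4f}\t"
                f"{d.ti}\t{d.tv}\n"
            )


def _write_fst(cfg, path, fm, overall, group_results) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("pop1\tpop2\tfst\tp\tnm\tnm_category\n")
        k = len(fm.populations)
        rows = [("ALL", "ALL", overall.fst, overall.p_value)]
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    (fm.populations[i], fm.populations[j],
                     float(fm.fst[i, j]), float(fm.p[i, j]))
                )
        if "amova" in group_results:
            g = group_results["amova"]
            rows.append(("|".join(group_results["units"]), "grouped",
                         g.fst, g.p_value))
        for a, b, f, p in rows:
            try:
                gf = differentiation.gene_flow(f)
                nm, cat = f"{gf.nm:.3f}", gf.category
            except ValueError:
                nm, cat = "NA", "NA"
            fh.write(f"{a}\t{b}\t{f:.3f}\t{p:.4f}\t{nm}\t{cat}\n")


def _write_amova(cfg, path, res) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("source\tdf\tssd\tvariance\tpct_variation\n")
        fh.write(
            f"among_populations\t{res.df_among}\t{res.ssd_among:.3f}\t"
            f"{res.sigma2_a:.3f}\t{res.pct_among:.2f}\n"
        )
        fh.write(
            f"within_populations\t{res.df_within}\t{res.ssd_within:.3f}\t"
            f"{res.sigma2_w:.3f}\t{res.pct_within:.2f}\n"
        )
        fh.write(f"# Phi_ST = {res.fst:.3f}\tp = {res.p_value:.4f}\t"
                 f"n_perm = {res.n_perm}\n")


def _write_neutrality(cfg, path, rows) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write(
            "population\tn\tti\ttv\tpi\ttajimas_D\tD_p\tfus_Fs\tFs_p\t"
            "tau\ttheta0\ttheta1\tssd\tt_years\n"
        )
        for (u, d, D, d_p, fs, fs_p, fit, et) in rows:
            fh.write(
                f"{u}\t{d.n}\t{d.ti}\t{d.tv}\t{d.pi:.4f}\t"
                f"{_fmt(D, 3)}\t{_fmt(d_p, 4)}\t{_fmt(fs, 3)}\t"
                f"{_fmt(fs_p, 4)}\t{fit.tau:.3f}\t{fit.theta0:.3f}\t"
                f"{fit.theta1:.3f}\t{fit.ssd:.6f}\t{et.t_years:.0f}\n"
            )
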