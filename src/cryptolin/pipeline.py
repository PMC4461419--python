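"""End-to-end orchestration: simulate (or load) -> population genetics ->
clustering -> hybrid classification -> haplotype network -> phenology ->
trait divergence -> report.

Every stage derives its seed deterministically from the global seed, so a
fixed configuration reproduces its report byte for byte.  A stage failure
preserves the partial report and raises with the stage name.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import bayesclust, haplonet, hybclass, io, phenostats, popgen, quantdiff, synthgen
from .datatypes import GenotypeMatrix

logger = logging.getLogger("cryptolin")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``simulate=True`` (default) inputs come from the synthetic
    generator; otherwise provide genepop/labels/fasta/schedule/traits
    paths.  MCMC lengths default to desk scale.
    """

    outdir: str = "cryptolin_run"
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    genepop: str | None = None
    labels: str | None = None  # CSV: individual,label
    fasta: str | None = None
    schedule: str | None = None
    traits: str | None = None
    k_min: int = 1
    k_max: int = 5
    cluster_replicates: int = 3
    cluster_burnin: int = 1000
    cluster_sweeps: int = 4000
    hybrid_burnin: int = 1000
    hybrid_sweeps: int = 6000
    hybrid_threshold: float = 0.95
    connection_limit: int = 7
    gap_mode: str = "indel_block_as_one"
    bootstrap_replicates: int = 200
    alpha: float = 0.05
    pst_c: float = 1.0
    pst_h2: float = 0.5
    phenology_pair: tuple[str, str] = ("eff1", "eff2")
    exclude_hybrids: bool = True

    def stage_seed(self, stage: int) -> int:
        child = np.random.SeedSequence(self.seed).spawn(16)[stage]
        return int(child.generate_state(1)[0] % (2**31 - 1))


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        sim_cfg = synthgen.SimulationConfig(seed=cfg.stage_seed(0), **cfg.sim_overrides)
        ds = synthgen.simulate_dataset(sim_cfg)
        return ds.genotypes, ds.labels, ds.haplotypes, ds.schedule, ds.traits, ds
    for name, path in (
        ("genepop", cfg.genepop),
        ("labels", cfg.labels),
    ):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")
    g, pops = io.read_genepop(cfg.genepop)
    labels = pd.read_csv(cfg.labels, index_col=0).iloc[:, 0].reindex(g.individuals)
    if labels.isna().any():
        raise ValueError("label file does not cover all genotyped individuals")
    haps = None
    if cfg.fasta and Path(cfg.fasta).exists():
        haps = haplonet.collapse_haplotypes(io.read_alignment_fasta(cfg.fasta))
    schedule = io.read_schedule_csv(cfg.schedule) if cfg.schedule else None
    traits = io.read_traits_csv(cfg.traits) if cfg.traits else None
    return g, labels, haps, schedule, traits, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write a JSON + Markdown report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    stage = "inputs"
    try:
        g, labels, haps, schedule, traits, ds = _load_inputs(cfg)
        labels = pd.Series(np.asarray(labels), index=g.individuals)
        if cfg.simulate:
            io.write_genepop(g, labels, outdir / "genotypes.gen")
            io.write_fasta(
                {ind: haps.sequences[h] for ind, h in haps.assignment.items()},
                outdir / "haplotypes.fasta",
            )
            io.write_schedule_csv(schedule, outdir / "schedule.csv")
            io.write_traits_csv(traits, outdir / "traits.csv")
            io.write_json(
                {"truth": ds.truth.to_dict(orient="index")}, outdir / "truth.json"
            )
        pure = labels != "hybrid" if cfg.exclude_hybrids else pd.Series(True, index=labels.index)
        lineages = [l for l in pd.unique(labels) if l != "hybrid"]

        stage = "popgen"
        logger.info("stage popgen")
        gp = g.subset(pure.to_numpy())
        lp = labels[pure].to_numpy()
        div = popgen.diversity_summary(gp, lp)
        fst = popgen.wc_fst(gp, lp)
        report["diversity"] = {
            str(k): {c: _r(v) for c, v in row.items()}
            for k, row in div.table().iterrows()
        }
        report["fst"] = {
            "multilocus_theta": _r(fst.theta),
            "pairwise": {
                f"{a}-{b}": _r(fst.pairwise.loc[a, b])
                for i, a in enumerate(lineages)
                for b in lineages[i + 1 :]
            },
        }
        dist = popgen.genotypic_distance_matrix(g)
        pco = popgen.pcoa(dist)
        coords = pd.DataFrame(
            pco.coordinates[:, :2], index=g.individuals, columns=["axis1", "axis2"]
        )
        coords["label"] = labels.to_numpy()
        coords.to_csv(outdir / "pcoa.csv", index_label="individual")
        report["pcoa_percent_first_two_axes"] = _r(float(pco.percent_variance[:2].sum()))

        stage = "cluster"
        logger.info("stage cluster")
        ll_table, runs = bayesclust.cluster_k_range(
            g,
            range(cfg.k_min, cfg.k_max + 1),
            replicates=cfg.cluster_replicates,
            burnin=cfg.cluster_burnin,
            sweeps=cfg.cluster_sweeps,
            seed=cfg.stage_seed(2),
        )
        dk = bayesclust.evanno_delta_k(ll_table)
        best_k = int(dk["delta_k"].idxmax())
        report["cluster"] = {
            "delta_k": {int(k): _r(v) for k, v in dk["delta_k"].dropna().items()},
            "best_k": best_k,
        }
        best_run = runs[(best_k, 0)]
        best_run.posterior.to_csv(outdir / "cluster_posterior.csv", index_label="individual")

        stage = "hybrids"
        logger.info("stage hybrids")
        hyb_summary = {}
        hyb_tables = []
        for i, a in enumerate(lineages):
            for b in lineages[i + 1 :]:
                members = labels.isin([a, b, "hybrid"]).to_numpy()
                sub = g.subset(members)
                sub_labels = labels[members]
                ref_a = list(sub_labels.index[sub_labels == a][:10])
                ref_b = list(sub_labels.index[sub_labels == b][:10])
                post = hybclass.classify_hybrids(
                    sub,
                    burnin=cfg.hybrid_burnin,
                    sweeps=cfg.hybrid_sweeps,
                    seed=cfg.stage_seed(3),
                    pure_a=ref_a,
                    pure_b=ref_b,
                    call_threshold=cfg.hybrid_threshold,
                )
                calls = post.calls()
                tab = post.posterior.copy()
                tab["call"] = calls
                tab["pair"] = f"{a}x{b}"
                hyb_tables.append(tab)
                hyb_summary[f"{a}x{b}"] = {
                    "n_hybrid_calls": int(
                        calls.isin(["F1", "F2", "BC_A", "BC_B"]).sum()
                    ),
                    "n_unassigned": int((calls == "unassigned").sum()),
                }
        pd.concat(hyb_tables).to_csv(outdir / "hybrid_posteriors.csv", index_label="individual")
        report["hybrids"] = hyb_summary

        stage = "network"
        logger.info("stage network")
        if haps is not None:
            net = haplonet.build_parsimony_network(
                haps, limit=cfg.connection_limit, gap_mode=cfg.gap_mode
            )
            net.edge_table().to_csv(outdir / "network_edges.csv", index=False)
            net.write_graphml(outdir / "network.graphml")
            report["network"] = {
                "n_haplotypes": len(haps.sequences),
                "n_components": len(net.components),
                "edges": [
                    [u, v, int(s)] for u, v, s in sorted(net.observed_edges())
                ],
            }

        stage = "phenology"
        logger.info("stage phenology")
        if schedule is not None:
            pa, pb = cfg.phenology_pair
            members = [
                ind
                for ind in schedule.individuals
                if schedule.lineage[ind] in (pa, pb)
            ]
            from .datatypes import FloweringSchedule

            sub = FloweringSchedule(
                schedule.values.loc[members].copy(), schedule.lineage.loc[members].copy()
            )
            seed_ph = cfg.stage_seed(4)
            phen = {}
            for lab in (pa, pb):
                res = phenostats.flowering_synchrony(
                    sub, "within", lab, n_boot=cfg.bootstrap_replicates, seed=seed_ph
                )
                phen[f"mean_r_within_{lab}"] = _ci_dict(res)
            phen["mean_r_between"] = _ci_dict(
                phenostats.flowering_synchrony(
                    sub, "between", n_boot=cfg.bootstrap_replicates, seed=seed_ph
                )
            )
            phen["mean_r_overall"] = _ci_dict(
                phenostats.flowering_synchrony(
                    sub, "overall", n_boot=cfg.bootstrap_replicates, seed=seed_ph
                )
            )
            n_a = int((labels == pa).sum())
            n_b = int((labels == pb).sum())
            probs = phenostats.hybrid_formation_probability(
                sub, pa, pb, n_a, n_b, n_boot=cfg.bootstrap_replicates, seed=seed_ph
            )
            for lab, res in probs.items():
                phen[f"p_hybrid_formation_{lab}"] = _ci_dict(res)
            report["phenology"] = phen

        stage = "traits"
        logger.info("stage traits")
        if traits is not None:
            tpure = quantdiff.TraitTable(
                traits.data[pure.reindex(traits.data.index).fillna(False)].copy()
            )
            trait_cols = [
                c
                for c in tpure.data.columns
                if c
                not in (
                    "lineage",
                    "damaged_capsules",
                    "total_capsules",
                    "soil_moisture",
                )
                and pd.api.types.is_numeric_dtype(tpure.data[c])
            ]
            tr = {}
            for col in trait_cols + ["soil_moisture"]:
                a = quantdiff.anova_oneway(tpure, col)
                _, letters = quantdiff.tukey_hsd(tpure, col, alpha=cfg.alpha)
                tr[col] = {"F": _r(a.F), "p": _r(a.p), "letters": letters}
            glm = quantdiff.quasibinomial_glm(
                tpure.data["damaged_capsules"],
                tpure.data["total_capsules"],
                tpure.groups,
            )
            tr["herbivory"] = {
                "dispersion": _r(glm.dispersion),
                "group_proportions": {k: _r(v) for k, v in glm.group_proportions.items()},
            }
            pa, pb = cfg.phenology_pair
            pair_mask = tpure.groups.isin([pa, pb])
            pst_res = quantdiff.pst_from_anova(
                tpure.data.loc[pair_mask, "first_flowering"],
                groups=tpure.groups[pair_mask],
                c=cfg.pst_c,
                h2=cfg.pst_h2,
            )
            tr["pst_first_flowering"] = {
                "value": _r(pst_res.value),
                "c": cfg.pst_c,
                "h2": cfg.pst_h2,
            }
            lda = quantdiff.lda_classify(tpure, trait_cols)
            tr["lda_correct_rate"] = {k: _r(v) for k, v in lda.correct_rate.items()}
            report["traits"] = tr

        stage = "report"
        io.write_json(report, outdir / "report.json")
        (outdir / "report.md").write_text(_markdown_report(report))
        report["report_hash"] = hashlib.sha256(
            (outdir / "report.json").read_bytes()
        ).hexdigest()
        return report
    except Exception as exc:
        io.write_json(report, outdir / "report.partial.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _r(x, nd: int = 6):
    return round(float(x), nd) if np.isfinite(x) else None


def _ci_dict(res) -> dict:
    out = {"value": _r(res.value)}
    if res.ci is not None:
        out["ci"] = [_r(res.ci.lower), _r(res.ci.upper)]
    return out


def _markdown_report(report: dict) -> str:
    lines = ["# cryptolin pipeline report", ""]
    if "diversity" in report:
        lines.append("## Diversity (pure individuals)")
        lines.append("group | H_E | A_R | F_IS")
        lines.append("--- | --- | --- | ---")
        for grp, row in report["diversity"].items():
            lines.append(
                f"{grp} | {row.get('H_E')} | {row.get('A_R')} | {row.get('F_IS')}"
            )
        lines.append("")
    if "fst" in report:
        lines.append("## Differentiation")
        for pair, v in report["fst"]["pairwise"].items():
            lines.append(f"- F_ST {pair}: {v}")
        lines.append("")
    if "cluster" in report:
        lines.append(f"## Clustering: best K = {report['cluster']['best_k']}")
        lines.append("")
    if "phenology" in report:
        lines.append("## Phenology")
        for k, v in report["phenology"].items():
            ci = f" (CI {v['ci'][0]}..{v['ci'][1]})" if "ci" in v else ""
            lines.append(f"- {k}: {v['value']}{ci}")
        lines.append("")
    if "traits" in report and "pst_first_flowering" in report["traits"]:
        lines.append(
            f"P_ST(first flowering) = {report['traits']['pst_first_flowering']['value']}"
        )
        lines.append("")
    return "\n".join(lines)
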