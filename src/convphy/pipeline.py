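"""One-config orchestration of the conversion-aware analysis.

Stage order follows the analysis logic of the study design: detect
converted tracts per paralogue group, partition alignments into converted
and conversion-free regions, build region-wise trees (conversion-free
regions recover the duplication history, converted regions cluster
paralogues), date duplications on conversion-free regions and conversions
on converted regions, run codon site models on full-length groups, check
codon-usage concordance, and scan for co-evolving residues on protein
alignments.  Every stochastic stage takes its seed from the single
top-level seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clock, codon, coevolution, diagnostics, geneconv, phylo, seqio, simulate
from .seqio import Alignment, CodonAlignment, RegionSpec
from .trees import Tree

log = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "regions", "diagnostics", "trees", "dating", "selection", "coevolution")


@dataclass
class StageReport:
    status: str  # ok | failed | skipped | disabled
    reason: str | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    config: dict
    stages: dict[str, StageReport]
    output_dir: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "output_dir": self.output_dir,
                "stages": {k: dataclasses.asdict(v) for k, v in self.stages.items()},
                "config": self.config,
            },
            indent=2,
            default=str,
        )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _stage_seed(base: int, stage: str) -> int:
    return (base * 1000003 + STAGES.index(stage) * 7919) % (2**31 - 1)


def run_pipeline(config: dict | str | Path) -> RunReport:
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(config.get("output_dir", "convphy_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    base_seed = int(config.get("seed", 0))
    enabled = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    reports: dict[str, StageReport] = {}

    def disabled(stage: str) -> bool:
        if not enabled[stage]:
            reports[stage] = StageReport("disabled")
            return True
        return False

    def skip(stage: str, reason: str) -> None:
        reports[stage] = StageReport("skipped", reason=reason)

    # ---- inputs / simulation -------------------------------------------
    alignment: CodonAlignment | None = None
    truth = None
    if config.get("simulate") and enabled["simulate"]:
        seed = _stage_seed(base_seed, "simulate")
        sim_cfg = config["simulate"]
        if sim_cfg.get("preset") == "tlr_family":
            sc = simulate.tlr_family_preset(seed=seed)
        elif "config_json" in sim_cfg:
            sc = simulate.SimConfig.from_json(Path(sim_cfg["config_json"]).read_text())
            sc = dataclasses.replace(sc, seed=seed)
        else:
            raise ValueError("simulate stage needs preset: tlr_family or config_json")
        alignment, truth = simulate.simulate_gene_family(sc)
        fasta = outdir / "simulated.fasta"
        seqio.write_fasta(alignment, fasta)
        (outdir / "sim_config.json").write_text(sc.to_json())
        truth_rows = [dataclasses.asdict(c) for c in truth.conversions]
        pd.DataFrame(truth_rows).to_csv(outdir / "truth_conversions.tsv", sep="\t", index=False)
        reports["simulate"] = StageReport(
            "ok", seed=seed, outputs=[str(fasta), str(outdir / "sim_config.json")]
        )
    else:
        if enabled["simulate"] and not config.get("simulate"):
            reports["simulate"] = StageReport("disabled", reason="no simulate block")
        elif not enabled["simulate"]:
            reports["simulate"] = StageReport("disabled")
        if "alignment" in config:
            alignment = seqio.read_codon_alignment(config["alignment"])
    if alignment is None:
        raise ValueError("no input: provide 'alignment' or a simulate block")

    groups: dict[str, dict] = config.get("groups") or {"all": {"ids": alignment.ids}}

    # ---- scan ----------------------------------------------------------
    tracts: dict[str, list[tuple[int, int]]] = {}
    scans: dict[str, geneconv.GroupScan] = {}
    if not disabled("scan"):
        seed = _stage_seed(base_seed, "scan")
        p = config.get("scan", {})
        rows = []
        try:
            for gname, g in groups.items():
                grp = alignment.subset(g["ids"])
                pairs = [tuple(x) for x in g.get("pairs", [])] or None
                scan = geneconv.scan_group(
                    grp, pairs=pairs, replicates=int(p.get("replicates", 10000)), seed=seed
                )
                scans[gname] = scan
                best = {}
                for f in scan.fragments:
                    best.setdefault(tuple(f.pair), f)
                for pr, f in best.items():
                    t = geneconv.call_converted_tracts(
                        scan, pr, alpha=float(p.get("alpha", 0.05)),
                        tract_match_prob=float(p.get("tract_match_prob", 0.95)),
                    )
                    if t:
                        tracts.setdefault(gname, []).append(t[0])
                        b, e = t[0]
                    else:
                        b, e = f.begin, f.end
                    # region columns implied by the called tract
                    rnames = {}
                    if b > 1:
                        rnames["N"] = f"1-{b - 1}"
                    if e >= grp.length - 200:
                        rnames["C"] = f"{b}-{grp.length}"
                    else:
                        rnames["Central"] = f"{b}-{e}"
                        rnames["C"] = f"{e + 1}-{grp.length}"
                    rows.append(
                        dict(
                            group=gname, pair=f"{pr[0]}:{pr[1]}", bcka_p=f.bcka_p,
                            sim_p=f.sim_p, N=rnames.get("N", "--"),
                            Central=rnames.get("Central", "--"), C=rnames.get("C", "--"),
                            n_poly=f.n_poly, n_dif=f.n_dif, tot_difs=f.tot_difs,
                        )
                    )
            out = outdir / "fragments.tsv"
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            reports["scan"] = StageReport("ok", seed=seed, params=dict(p), outputs=[str(out)])
        except Exception as exc:  # stage isolation
            reports["scan"] = StageReport("failed", reason=str(exc))

    # ---- regions -------------------------------------------------------
    regions: dict[str, list[RegionSpec]] = {}
    if not disabled("regions"):
        if reports.get("scan", StageReport("disabled")).status != "ok":
            skip("regions", "scan did not run")
        else:
            for gname, g in groups.items():
                L = alignment.subset(g["ids"]).length
                gtr = sorted(tracts.get(gname, []), key=lambda t: t[0] - t[1])
                if gtr:
                    b, e = gtr[0]
                    regs = []
                    if b > 1:
                        regs.append(RegionSpec("N", 1, b - 1))
                    regs.append(RegionSpec("C" if e >= L - 200 else "Central", b, e))
                    if e < L - 200:
                        regs.append(RegionSpec("C", e + 1, L))
                    regions[gname] = regs
                else:
                    regions[gname] = [RegionSpec("N", 1, L)]
            rows = [
                dict(group=g, name=r.name, start=r.start, end=r.end)
                for g, regs in regions.items()
                for r in regs
            ]
            out = outdir / "regions.tsv"
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            reports["regions"] = StageReport("ok", outputs=[str(out)])

    # ---- diagnostics (concordance + saturation) -------------------------
    if not disabled("diagnostics"):
        try:
            rows = []
            for gname, g in groups.items():
                grp = alignment.subset(g["ids"])
                regs = regions.get(gname) or [RegionSpec("N", 1, grp.length)]
                pairs = [tuple(x) for x in g.get("pairs", [])] or [
                    (a, b) for i, a in enumerate(g["ids"]) for b in g["ids"][i + 1 :]
                ]
                for pr in pairs:
                    rep = diagnostics.codon_usage_concordance(grp, pr, regs)
                    verdict = diagnostics.conversion_vs_convergence_verdict(
                        rep, candidate_region=regs[-1].name
                    )
                    for r in rep.regions:
                        rows.append(
                            dict(group=gname, pair=f"{pr[0]}:{pr[1]}", region=r.name,
                                 n_conserved=r.n_conserved, n_identical_codon=r.n_identical_codon,
                                 fraction=r.fraction, verdict=verdict)
                        )
            out = outdir / "concordance.tsv"
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            sat = diagnostics.saturation_table(alignment)
            sat_out = outdir / "saturation.tsv"
            pd.DataFrame(
                [dict(pair=f"{r.pair[0]}:{r.pair[1]}", s=r.s, v=r.v, d=r.d) for r in sat.records]
            ).to_csv(sat_out, sep="\t", index=False)
            reports["diagnostics"] = StageReport("ok", outputs=[str(out), str(sat_out)])
        except Exception as exc:
            reports["diagnostics"] = StageReport("failed", reason=str(exc))

    # ---- trees -----------------------------------------------------------
    region_alignments: dict[tuple[str, str], CodonAlignment] = {}
    if not disabled("trees"):
        if reports.get("regions", StageReport("disabled")).status != "ok":
            skip("trees", "regions not available")
        else:
            seed = _stage_seed(base_seed, "trees")
            p = config.get("trees", {})
            outs = []
            try:
                for gname, g in groups.items():
                    grp = alignment.subset(g["ids"])
                    parts = seqio.partition_regions(grp, regions[gname])
                    for rname, sub in parts.items():
                        region_alignments[(gname, rname)] = sub
                        tree, support = phylo.bootstrap_support(
                            sub,
                            tree_builder=lambda a: phylo.nj_tree(a, "f84"),
                            replicates=int(p.get("bootstrap_replicates", 1000)),
                            seed=seed,
                        )
                        path = outdir / f"tree_{gname}_{rname}.nwk"
                        path.write_text(tree.to_newick())
                        outs.append(str(path))
                reports["trees"] = StageReport("ok", seed=seed, params=dict(p), outputs=outs)
            except Exception as exc:
                reports["trees"] = StageReport("failed", reason=str(exc))

    # ---- dating ----------------------------------------------------------
    if not disabled("dating"):
        p = config.get("dating", {})
        if reports.get("trees", StageReport("disabled")).status != "ok":
            skip("dating", "trees stage did not run")
        elif not p.get("calibrations"):
            skip("dating", "no calibrations configured")
        else:
            try:
                cals = [
                    clock.Calibration(tuple(c["leaves"]), float(c["min_age"]), float(c["max_age"]))
                    for c in p["calibrations"]
                ]
                rows = []
                for gname, g in groups.items():
                    free = region_alignments.get((gname, "N"))
                    if free is None:
                        continue
                    tree = Tree.from_newick(p["tree"]) if "tree" in p else phylo.nj_tree(free)
                    tree = _root_by_outgroup(tree, p.get("outgroup"))
                    fit = clock.fit_clock(
                        free, tree, cals, model=p.get("model", "global"),
                        data_type=p.get("data_type", "codon"),
                    )
                    for cl_set, age in fit.node_ages.items():
                        rows.append(
                            dict(group=gname, clade=";".join(sorted(cl_set)), age_mya=age,
                                 rate=fit.rates[0], model=fit.model)
                        )
                out = outdir / "node_ages.tsv"
                pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
                reports["dating"] = StageReport("ok", params=dict(p), outputs=[str(out)])
            except Exception as exc:
                reports["dating"] = StageReport("failed", reason=str(exc))

    # ---- selection --------------------------------------------------------
    if not disabled("selection"):
        p = config.get("selection", {})
        try:
            fit_rows, lrt_rows, site_rows = [], [], []
            models = p.get("models", ["M0", "M1a", "M2a", "M7", "M8", "M8a"])
            for gname, g in groups.items():
                ids = p.get("ids", {}).get(gname, g["ids"]) if isinstance(p.get("ids"), dict) else g["ids"]
                grp = alignment.subset(ids)
                start_tree = phylo.nj_tree(grp, "f84")
                fits = codon.fit_model_series(
                    grp, start_tree, models=models, n_starts=int(p.get("n_starts", 2))
                )
                for m, f in fits.items():
                    fit_rows.append(
                        dict(group=gname, model=m, lnl=f.lnl, kappa=f.kappa,
                             params=json.dumps({k: round(v, 5) for k, v in f.params.items()}),
                             proportion_positive=f.proportion_positive,
                             omega_positive=f.omega_positive())
                    )
                for null, alt in (("M1a", "M2a"), ("M7", "M8"), ("M8a", "M8")):
                    if null in fits and alt in fits:
                        t = codon.lrt(fits[null], fits[alt])
                        lrt_rows.append(
                            dict(group=gname, test=f"{null} vs. {alt}", statistic=round(t.statistic, 4),
                                 df=t.df, pvalue=t.pvalue, boundary_pvalue=t.boundary_pvalue)
                        )
                ref = p.get("reference", ids[0])
                if "M8" in fits and fits["M8"].positive_class_mask.any():
                    tab = codon.positively_selected_sites(fits["M8"], grp, ref)
                    for r in tab.selected(float(p.get("threshold", 0.9))):
                        site_rows.append(dict(group=gname, model="M8", site=r.label, p=r.p_positive))
            outs = []
            for nm, rows in (("model_fits", fit_rows), ("lrt", lrt_rows), ("selected_sites", site_rows)):
                path = outdir / f"{nm}.tsv"
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                outs.append(str(path))
            reports["selection"] = StageReport("ok", params=dict(p), outputs=outs)
        except Exception as exc:
            reports["selection"] = StageReport("failed", reason=str(exc))

    # ---- coevolution -------------------------------------------------------
    if not disabled("coevolution"):
        p = config.get("coevolution", {})
        if not p:
            skip("coevolution", "no coevolution block configured")
        else:
            seed = _stage_seed(base_seed, "coevolution")
            try:
                ids = p.get("ids", alignment.ids)
                prot = alignment.subset(ids).to_protein()
                scan = coevolution.coevolution_scan(
                    prot,
                    n_samplings=int(p.get("n_samplings", 10000)),
                    alpha=float(p.get("alpha", 0.001)),
                    seed=seed,
                    name_a=p.get("name", "protein"),
                )
                rows = [
                    dict(protein_a=q.protein_a, site_a=q.site_a, residue_a=q.residue_a,
                         protein_b=q.protein_b, site_b=q.site_b, residue_b=q.residue_b,
                         r=q.r, p=q.p, mode=q.mode)
                    for q in scan.pairs
                ]
                out = outdir / "coevolution_pairs.tsv"
                pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
                outs = [str(out)]
                if scan.pairs:
                    gml, sif = outdir / "coevolution.graphml", outdir / "coevolution.sif"
                    coevolution.export_network(scan.pairs, gml, sif)
                    outs += [str(gml), str(sif)]
                reports["coevolution"] = StageReport("ok", seed=seed, params=dict(p), outputs=outs)
            except Exception as exc:
                reports["coevolution"] = StageReport("failed", reason=str(exc))

    report = RunReport(config=config, stages=reports, output_dir=str(outdir))
    (outdir / "run_report.json").write_text(report.to_json())
    return report


def _root_by_outgroup(tree: Tree, outgroup: str | None) -> Tree:
    """Root an unrooted NJ tree.  With an outgroup leaf, root on its edge;
    otherwise midpoint-like: root on the longest edge."""
    t = tree.copy()
    if len(t.root.children) == 2:
        return t
    target = None
    if outgroup is not None:
        target = next(n for n in t.postorder() if n.name == outgroup)
    else:
        target = max(
            (n for n in t.postorder() if n.parent is not None), key=lambda n: n.length or 0.0
        )
    # re-root on the edge above `target`
    from .trees import Node

    old_parent = target.parent
    old_parent.children.remove(target)
    target.parent = None
    new_root = Node()
    half = (target.length or 0.0) / 2
    target.length = half
    new_root.add(target)
    # invert the path from old_parent up to the old root
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    orig_len = [n.length for n in path]
    for child, parent in zip(path, path[1:]):
        parent.children.remove(child)
        child.parent = None
    for i, (child, parent) in enumerate(zip(path, path[1:])):
        child.add(parent)
        parent.length = orig_len[i]
    path[0].length = half
    new_root.add(path[0])
    return Tree(new_root)
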