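"""End-to-end orchestration of the study workflow.

``run_all`` executes partition -> diversity -> assembly -> network ->
drivers for each taxa scope (total, abundant, rare), writes every stage's
outputs under ``<out>/<scope>/<stage>/`` and records a manifest (seeds,
thresholds, stage wall times) sufficient to reproduce any number bit-
exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assembly as asm
from . import diversity as div
from . import drivers as drv
from . import io as eio
from . import network as net
from . import partition as part

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds of one pipeline run."""

    table_path: str
    metadata_path: str
    out_dir: str
    tree_path: str | None = None
    env_path: str | None = None
    abundant_thresh: float = part.DEFAULT_ABUNDANT_THRESH
    rare_thresh: float = part.DEFAULT_RARE_THRESH
    rho_thresh: float = 0.8
    p_thresh: float = 0.01
    top_n_otus: int = 250
    n_null: int = 999
    n_perm: int = 999
    seed: int = 0
    alpha_index: str = "shannon"
    scopes: tuple[str, ...] = ("total", "abundant", "rare")
    run_assembly: bool = True
    run_network: bool = True
    run_drivers: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "scopes" in raw:
            raw["scopes"] = tuple(raw["scopes"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = {"seconds": round(dt, 3),
                                        "ok": exc is None}
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
    return _Ctx()


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage for every scope; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(cfg).items()},
                      "stages": {}}

    table = eio.read_community(cfg.table_path, cfg.metadata_path)
    rel = eio.to_relative(table)
    tree = eio.read_tree(cfg.tree_path) if cfg.tree_path else None
    env = eio.read_env(cfg.env_path) if cfg.env_path else None
    if cfg.run_assembly and tree is None:
        raise StageError("stage 'assembly' requires a tree "
                         "(tree_path is not set)")

    with _stage(manifest, "partition"):
        presult = part.build_partition(rel, cfg.abundant_thresh, cfg.rare_thresh)
        pdir = out / "partition"
        pdir.mkdir(exist_ok=True)
        presult.labels.T.to_csv(pdir / "labels.tsv", sep="\t")
        if presult.abundant is not None:
            presult.abundant.data.to_csv(pdir / "abundant.tsv", sep="\t")
        if presult.rare is not None:
            presult.rare.data.to_csv(pdir / "rare.tsv", sep="\t")

    scope_tables = {"total": rel}
    scope_counts = {"total": table}
    if presult.abundant is not None:
        scope_tables["abundant"] = eio.to_relative(presult.abundant)
    if presult.rare is not None:
        scope_tables["rare"] = eio.to_relative(presult.rare)

    for scope in cfg.scopes:
        if scope not in scope_tables:
            logger.warning("scope %s empty after partition; skipped", scope)
            continue
        stab = scope_tables[scope]
        sdir = out / scope
        sdir.mkdir(exist_ok=True)

        with _stage(manifest, f"{scope}/diversity"):
            ddir = sdir / "diversity"
            ddir.mkdir(exist_ok=True)
            alpha = div.alpha_diversity(stab)
            alpha.values.to_csv(ddir / "alpha.tsv", sep="\t")
            bc = div.bray_curtis(stab)
            bc.matrix.to_csv(ddir / "braycurtis.tsv", sep="\t")
            if len(stab.sample_ids) >= 4:
                coords, stress = div.nmds(bc, seed=cfg.seed)
                coords.assign(stress=stress).to_csv(ddir / "nmds.tsv", sep="\t")
            group_sizes = stab.groups.value_counts()
            if len(group_sizes) >= 2 and (group_sizes >= 2).all():
                pm = div.permanova(bc, stab.groups, n_perm=cfg.n_perm,
                                   seed=cfg.seed)
                (ddir / "permanova.txt").write_text(json.dumps(pm, indent=2))
            else:
                logger.warning("scope %s: too few samples per group for "
                               "PERMANOVA; skipped", scope)

        if cfg.run_assembly and scope == "total":
            with _stage(manifest, f"{scope}/assembly"):
                adir = sdir / "assembly"
                adir.mkdir(exist_ok=True)
                pw = asm.pairwise_assembly(scope_counts[scope], tree,
                                           n_null=cfg.n_null, seed=cfg.seed)
                eio.write_pairwise(pw, adir / "pairwise.tsv")
                asm.summarize_assembly(pw, "all").table.to_csv(
                    adir / "summary_all.tsv", sep="\t")
                asm.summarize_assembly(pw, "per-group").table.to_csv(
                    adir / "summary_by_group.tsv", sep="\t")

        if cfg.run_network:
            with _stage(manifest, f"{scope}/network"):
                ndir = sdir / "network"
                ndir.mkdir(exist_ok=True)
                topo_rows = {}
                for group in stab.group_labels():
                    if len(stab.samples_in_group(group)) < 5:
                        logger.warning("group %s: <5 samples, network skipped",
                                       group)
                        continue
                    sub = net.select_top_otus(stab, group, n=cfg.top_n_otus)
                    conet = net.build_network(sub, cfg.rho_thresh, cfg.p_thresh)
                    if conet.n_nodes == 0:
                        logger.warning("group %s: empty network", group)
                        continue
                    net.detect_modules(conet, seed=cfg.seed)
                    topo_rows[group] = net.topology(conet).to_series()
                    net.zi_pi(conet).to_csv(ndir / f"nodes_{group}.tsv", sep="\t")
                    eio.write_gexf(conet, ndir / f"network_{group}.gexf",
                                   ndir / f"network_{group}.graphml")
                    if conet.n_nodes >= 3:
                        for mode in ("random", "targeted"):
                            net.robustness(conet, mode=mode, seed=cfg.seed,
                                           n_reps=50).to_frame().to_csv(
                                ndir / f"robustness_{mode}_{group}.tsv",
                                sep="\t", index=False)
                if topo_rows:
                    pd.DataFrame(topo_rows).T.to_csv(ndir / "topology.tsv",
                                                     sep="\t")

        if cfg.run_drivers and env is not None:
            n_factors = env.data.shape[1]
            if len(stab.sample_ids) < n_factors + 2:
                logger.warning("scope %s: %d samples cannot support a "
                               "%d-factor fit; drivers skipped", scope,
                               len(stab.sample_ids), n_factors)
                continue
            with _stage(manifest, f"{scope}/drivers"):
                vdir = sdir / "drivers"
                vdir.mkdir(exist_ok=True)
                senv = eio.EnvTable(env.data.loc[stab.sample_ids])
                alpha = div.alpha_diversity(stab)
                resp = alpha.values[cfg.alpha_index]
                imp = drv.lmg_importance(senv, resp)
                pd.DataFrame({"share": imp.shares,
                              "share_pct": imp.share_pct,
                              "sign": imp.univariate_sign}).to_csv(
                    vdir / "importance.tsv", sep="\t")
                drv.univariate_trends(senv, resp).to_csv(
                    vdir / "univariate.tsv", sep="\t")
                fit = drv.envfit_mc(stab, senv, n_perm=cfg.n_perm, seed=cfg.seed)
                fit.table.assign(axis1_pct=fit.axis_variance_pct[0],
                                 axis2_pct=fit.axis_variance_pct[1]).to_csv(
                    vdir / "envfit.tsv", sep="\t")
                if cfg.run_assembly and scope == "total":
                    rows = {f: drv.bnti_env_regression(
                        pw, senv, f, n_perm=cfg.n_perm, seed=cfg.seed)
                        for f in senv.data.columns}
                    pd.DataFrame(rows).T.to_csv(vdir / "bnti_env.tsv", sep="\t")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
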