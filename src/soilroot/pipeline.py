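"""End-to-end pipeline: partition, flow, diversity, assembly models and
networks from one validated configuration, with a machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assembly import compare_niche_breadth, fit_ncm, niche_breadth
from .diversity import alpha_compare, alpha_diversity, bray_curtis, pcoa, permanova, rarefy
from .flow import classify_flow
from .io_tables import (
    CountMatrix,
    SampleMetadata,
    ValidationError,
    aggregate_by_rank,
    read_count_table,
    read_metadata,
    read_taxonomy,
    relative_abundance,
)
from .network import build_network, network_topology, robustness_curve, write_edge_list
from .partition import classify_abundance, partition_summary

logger = logging.getLogger(__name__)

ALL_STAGES = ("partition", "flow", "diversity", "assembly", "network")

_KNOWN_KEYS = {
    "counts", "metadata", "taxonomy", "abundant_threshold", "rare_threshold",
    "flow_alpha", "network_r", "network_p", "network_rank", "rarefy_depth",
    "seed", "n_permutations", "stages", "collapse_bulk",
}


@dataclass
class PipelineConfig:
    counts: str = ""
    metadata: str = ""
    taxonomy: str | None = None
    abundant_threshold: float = 0.01
    rare_threshold: float = 0.0001
    flow_alpha: float = 0.05
    network_r: float = 0.6
    network_p: float = 0.01
    network_rank: str = "genus"
    rarefy_depth: int | None = None
    seed: int = 0
    n_permutations: int = 999
    stages: tuple = ALL_STAGES
    collapse_bulk: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rare_threshold < self.abundant_threshold < 1:
            raise ValidationError(
                "thresholds must satisfy 0 < rare < abundant < 1, got "
                f"rare={self.rare_threshold}, abundant={self.abundant_threshold}"
            )
        for name in ("flow_alpha", "network_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_proportion(value) -> float:
    """Accept '1%' style strings for threshold fields."""
    if isinstance(value, str) and value.strip().endswith("%"):
        return float(value.strip()[:-1]) / 100.0
    return float(value)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and normalize a YAML/JSON pipeline configuration."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ValidationError(f"malformed config{line}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError("config must be a mapping")
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("abundant_threshold", "rare_threshold"):
        if key in doc:
            doc[key] = _as_proportion(doc[key])
    if "stages" in doc:
        doc["stages"] = tuple(doc["stages"])
    return PipelineConfig(**doc)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# soilroot {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    cm: CountMatrix | None = None,
    md: SampleMetadata | None = None,
) -> dict:
    """Run all enabled stages; returns (and writes) the report dict.

    ``cm``/``md`` may be passed directly (e.g. synthetic data); otherwise
    they are loaded from the configured paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    if cm is None:
        cm = read_count_table(cfg.counts)
    if md is None:
        md = read_metadata(cfg.metadata)
    missing = set(cm.sample_ids) - set(md.sample_ids)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(missing)}")
    tax = read_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
    if cfg.rarefy_depth:
        cm = rarefy(cm, cfg.rarefy_depth, seed=cfg.seed)
    ra = relative_abundance(cm)
    groups = md.groups(collapse_bulk=cfg.collapse_bulk)
    varieties = sorted(set(md.table["variety"]))
    compartments = md.table["compartment"]
    report: dict = {
        "version": __version__,
        "config_hash": h,
        "seed": cfg.seed,
        "groups": sorted(groups),
        "stages": list(cfg.stages),
        "outputs": [],
    }

    def record(name: str) -> Path:
        report["outputs"].append(name)
        return out / name

    try:
        if "partition" in cfg.stages:
            parts = classify_abundance(
                ra, md, cfg.abundant_threshold, cfg.rare_threshold,
                collapse_bulk=cfg.collapse_bulk,
            )
            summ = partition_summary(parts)
            _write_tsv(summ.formatted(), record("partition_summary.tsv"), h)
            per_otu = pd.DataFrame({g: p.classes for g, p in parts.items()})
            _write_tsv(per_otu, record("partition_classes.tsv"), h)

        if "flow" in cfg.stages:
            transitions = []
            for v in varieties:
                if "bulk_soil" in set(compartments):
                    src = "bulk_soil" if cfg.collapse_bulk else f"bulk_soil:{v}"
                    transitions.append((src, f"rhizosphere:{v}"))
                transitions.append((f"rhizosphere:{v}", f"endosphere:{v}"))
            flow_counts = {}
            for src, tgt in transitions:
                fr = classify_flow(ra, md, src, tgt, alpha=cfg.flow_alpha)
                tag = f"{src}_to_{tgt}".replace(":", "-")
                _write_tsv(fr.table, record(f"flow_{tag}.tsv"), h)
                flow_counts[f"{src}->{tgt}"] = fr.counts().to_dict()
            report["flow_counts"] = flow_counts

        if "diversity" in cfg.stages:
            alpha = alpha_diversity(cm)
            _write_tsv(alpha, record("alpha_diversity.tsv"), h)
            glabels = pd.Series(
                {s: md.group_label(s, cfg.collapse_bulk) for s in cm.sample_ids}
            )
            comparisons = pd.concat(
                [
                    alpha_compare(alpha[idx], glabels).assign(index=idx)
                    for idx in ("chao1", "shannon")
                ]
            )
            _write_tsv(comparisons, record("alpha_comparisons.tsv"), h, index=False)
            bc = bray_curtis(ra)
            _write_tsv(bc, record("bray_curtis.tsv"), h)
            ord_res = pcoa(bc)
            _write_tsv(ord_res.coordinates, record("pcoa_coordinates.tsv"), h)
            perm = permanova(
                bc, compartments, n_permutations=cfg.n_permutations,
                seed=cfg.seed, factor="compartment",
            )
            report["permanova"] = {
                "factor": perm.factor, "pseudo_F": perm.pseudo_f,
                "R2": perm.r_squared, "p": perm.pvalue,
            }
            report["pcoa_variance_explained"] = [
                round(float(v), 4) for v in ord_res.variance_explained[:2]
            ]

        if "assembly" in cfg.stages:
            ncm_rows = {}
            for g, members in groups.items():
                if len(members) < 5:
                    logger.warning("group %s has < 5 samples; NCM fit skipped", g)
                    continue
                fit = fit_ncm(cm.subset_samples(members))
                ncm_rows[g] = {
                    "m": fit.m, "N": fit.N, "Nm": fit.Nm, "R2": fit.r_squared,
                    **{f"n_{k}": int(v) for k, v in fit.partition_counts().items()},
                }
                tag = g.replace(":", "-")
                _write_tsv(fit.table, record(f"ncm_{tag}.tsv"), h)
            report["ncm"] = ncm_rows
            b_by_group = {
                g: niche_breadth(ra.subset_samples(members))
                for g, members in groups.items()
                if len(members) >= 2
            }
            nb = pd.DataFrame({g: b for g, b in b_by_group.items()})
            _write_tsv(nb, record("niche_breadth.tsv"), h)
            _write_tsv(
                compare_niche_breadth({g: b.dropna() for g, b in b_by_group.items()}),
                record("niche_breadth_comparisons.tsv"), h, index=False,
            )

        if "network" in cfg.stages:
            if tax is not None:
                level = aggregate_by_rank(cm, tax, cfg.network_rank)
                level_ra = relative_abundance(level)
            else:
                level_ra = ra
            net_metrics = {}
            for g, members in groups.items():
                if len(members) < 5:
                    logger.warning("group %s has < 5 samples; network skipped", g)
                    continue
                net = build_network(
                    level_ra.data.loc[members], r_threshold=cfg.network_r,
                    p_threshold=cfg.network_p, group=g,
                )
                tag = g.replace(":", "-")
                write_edge_list(net, record(f"network_edges_{tag}.tsv"))
                if net.number_of_nodes() >= 2:
                    net_metrics[g] = network_topology(net)
                    curve = robustness_curve(net, "random", seed=cfg.seed)
                    _write_tsv(
                        curve.table, record(f"network_robustness_{tag}.tsv"), h,
                        index=False,
                    )
                else:
                    net_metrics[g] = {"nodes": net.number_of_nodes(), "edges": 0}
            report["network"] = net_metrics
    except Exception as exc:
        report["failed"] = True
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
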