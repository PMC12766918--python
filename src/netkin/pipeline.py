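"""One-shot pipeline: network + annotations -> partition, overrepresentation
table, domains, evaluation report, figure, and a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .annotation import build_matrix, read_annotations
from .clustering import cluster, write_partition
from .domains import build_domains, unique_clusters
from .evaluation import compactness, separation, silhouette
from .graph_io import read_network
from .stats import run_overrep
from .viz import PlotSpec, layout, render

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration mirroring every CLI flag."""

    network: str = ""
    annotations: str = ""
    out_dir: str = "netkin_out"
    network_fmt: str = "auto"
    annotation_fmt: str = "auto"
    min_size: int = 2
    max_size: int | None = None
    annotated_universe: bool = False
    algorithm: str = "louvain"
    gamma: float = 1.0
    inflation: float = 2.0
    seed: int = 42
    test: str = "hypergeom"
    alpha: float = 0.01
    correction: str = "none"
    permutations: int = 1000
    top_k: int = 3
    layout: str = "fruchterman-reingold"
    layout_seed: int = 42
    contour_level: float = 0.67
    figure_format: str = "svg"
    dpi: int = 150

    _KNOWN = None  # populated below

    def validate(self) -> None:
        if not self.network:
            raise ConfigError("config requires 'network'")
        if not self.annotations:
            raise ConfigError("config requires 'annotations'")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.contour_level < 1:
            raise ConfigError("contour_level must be in (0, 1)")
        if self.correction not in ("bh", "bonferroni", "none"):
            raise ConfigError(f"unknown correction {self.correction!r}")
        if self.test not in ("permutation", "hypergeom", "chisq", "binom"):
            raise ConfigError(f"unknown test {self.test!r}")
        if self.min_size < 1:
            raise ConfigError("min_size must be >= 1")
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Artifacts: partition.tsv, overrep.tsv, domains.tsv, report.json, a
    figure (figure.<fmt>), and manifest.json with config, seeds, package
    versions, and input checksums. Any stage error aborts with the stage
    name attached.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        logger.info("stage %s: start", name)
        try:
            result = fn(*args, **kw)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        logger.info("stage %s: done", name)
        return result

    net = stage("read_network", read_network, cfg.network, cfg.network_fmt)
    mapping = stage("read_annotations", read_annotations, cfg.annotations,
                    cfg.annotation_fmt)
    matrix = stage(
        "build_matrix", build_matrix, mapping, net,
        min_size=cfg.min_size, max_size=cfg.max_size,
        annotated_universe=cfg.annotated_universe,
    )
    part = stage(
        "cluster", cluster, net, cfg.algorithm,
        gamma=cfg.gamma, seed=cfg.seed, inflation=cfg.inflation,
    )
    stage("write_partition", write_partition, part, out / "partition.tsv")

    tab = stage(
        "overrep", run_overrep, matrix, part,
        test=cfg.test, alpha=cfg.alpha, correction=cfg.correction,
        R=cfg.permutations, seed=cfg.seed,
    )
    tab_out = tab.copy()
    tab_out["p"] = tab_out["p"].map("{:.10g}".format)
    tab_out["adj_p"] = tab_out["adj_p"].map("{:.10g}".format)
    stage(
        "write_overrep",
        lambda: tab_out.to_csv(out / "overrep.tsv", sep="\t", index=False),
    )

    dm = stage("domains", build_domains, tab, alpha=cfg.alpha, top_k=cfg.top_k)
    uniq = (
        stage("unique_clusters", unique_clusters, dm, part, matrix)
        if dm.significant_clusters
        else set()
    )
    with open(out / "domains.tsv", "w") as fh:
        fh.write("cluster\trank\tterm\tp\tunique\n")
        for cid in sorted(dm.significant_clusters):
            for rank, (term, p) in enumerate(dm.labels[cid]):
                fh.write(
                    f"{cid}\t{rank}\t{term}\t{p:.10g}\t{int(cid in uniq)}\n"
                )

    coords = stage("layout", layout, net, cfg.layout, cfg.layout_seed)
    report = {
        "n_nodes": net.n,
        "n_edges": net.m,
        "n_terms": matrix.n_terms,
        "annotation_coverage": matrix.coverage,
        "k_clusters": part.k,
        "n_significant_clusters": len(dm.significant_clusters),
        "n_unique_clusters": len(uniq),
        "per_cluster_compactness": {
            str(k): v for k, v in compactness(coords, part).items()
        },
        "separation": separation(coords, part) if part.k >= 2 else None,
        "silhouette_mean": silhouette(coords, part)[0] if part.k >= 2 else None,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    spec = PlotSpec(
        layout=cfg.layout, layout_seed=cfg.layout_seed,
        contour_level=cfg.contour_level, format=cfg.figure_format, dpi=cfg.dpi,
    )
    fig_path = out / f"figure.{cfg.figure_format}"
    stage("render", render, net, coords, dm, spec, fig_path, part)

    manifest = {
        "config": {k: v for k, v in asdict(cfg).items() if not k.startswith("_")},
        "versions": {
            "netkin": __version__,
            "python": sys.version.split()[0],
        },
        "inputs": {
            "network_sha256": _sha256(Path(cfg.network)),
            "annotations_sha256": _sha256(Path(cfg.annotations)),
        },
        "artifacts": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
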