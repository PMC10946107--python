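"""End-to-end pipeline: counts in, rewiring score table out.

Stages (all library functions, reusable individually):

0. normalise counts to relative abundance, drop unclassified taxa;
1. estimate correlations per group, threshold into weighted networks,
   prune taxa isolated in both;
2. Louvain-cluster each network, unify similar taxa under the taxonomy
   constraint, choose representatives, contract both networks (skippable);
3. one-sided rank test per representative, keep those significantly
   increased in the focus group as core taxa;
4. restrict both networks to core taxa and their neighbours;
5. compute the per-node rewiring index and assemble the feature table.

``run`` works on in-memory tables and returns a :class:`PipelineResult`;
``run_pipeline`` adds file I/O, output writing, and a JSON manifest that
records the configuration so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contraction as _contraction
from . import core_selection as _core
from . import correlation as _correlation
from . import rewiring as _rewiring
from . import tables_io as _tables
from .network import WeightedNetwork, difference_network

__all__ = ["RunConfig", "PipelineResult", "run", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """File-level configuration of one pipeline run."""

    counts_x: str
    counts_y: str
    taxonomy: str
    out_dir: str
    focus: str = "Y"
    edge_threshold: float = _correlation.DEFAULT_EDGE_THRESHOLD
    p_threshold: float = _core.DEFAULT_P_THRESHOLD
    seed: int = 0
    backend: str = "sparcc"
    sparcc_iterations: int = 20
    skip_contraction: bool = False
    contract_mean: str = "edges"
    unclassified_labels: tuple[str, ...] = tuple(
        sorted(_tables.DEFAULT_UNCLASSIFIED_LABELS)
    )
    precomputed_x: str | None = None
    precomputed_y: str | None = None
    plot: bool = False


@dataclass
class PipelineResult:
    """All intermediate and final artefacts of one run."""

    abundance_x: _tables.AbundanceTable
    abundance_y: _tables.AbundanceTable
    net_x: WeightedNetwork  # effective (pruned) network, group X
    net_y: WeightedNetwork
    effective_taxa: list[str]
    cmap: _contraction.ContractionMap
    contracted_x: WeightedNetwork
    contracted_y: WeightedNetwork
    core: _core.CoreSet
    pair: _rewiring.SubnetworkPair
    scores: pd.DataFrame


def _stage(name: str):
    """Decorator: re-raise stage failures with the stage name attached."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run(
    ct_x: _tables.CountTable,
    ct_y: _tables.CountTable,
    taxonomy: _tables.Taxonomy,
    *,
    focus: str = "Y",
    edge_threshold: float = _correlation.DEFAULT_EDGE_THRESHOLD,
    p_threshold: float = _core.DEFAULT_P_THRESHOLD,
    seed: int = 0,
    backend: str = "sparcc",
    sparcc_options: _correlation.SparccOptions | None = None,
    skip_contraction: bool = False,
    contract_mean: str = "edges",
    unclassified_labels=_tables.DEFAULT_UNCLASSIFIED_LABELS,
    precomputed_x=None,
    precomputed_y=None,
) -> PipelineResult:
    """Run the full method on in-memory count tables."""
    _tables.warn_on_sample_overlap(ct_x, ct_y)

    # Step 0: normalisation, then unclassified removal (order matters)
    at_x = _tables.drop_unclassified(
        _tables.to_relative_abundance(ct_x), unclassified_labels
    )
    at_y = _tables.drop_unclassified(
        _tables.to_relative_abundance(ct_y), unclassified_labels
    )
    keep = at_x.taxa
    ct_x = _tables.CountTable(ct_x.group, ct_x.data.loc[keep])
    ct_y = _tables.CountTable(ct_y.group, ct_y.data.loc[keep])

    # Step 1: correlations -> thresholded networks -> joint-isolate pruning
    cm_x = _correlation.estimate_correlations(
        ct_x, backend=backend, seed=seed, options=sparcc_options,
        precomputed=precomputed_x,
    )
    cm_y = _correlation.estimate_correlations(
        ct_y, backend=backend, seed=seed + 1, options=sparcc_options,
        precomputed=precomputed_y,
    )
    full_x = _correlation.threshold_to_network(cm_x, edge_threshold)
    full_y = _correlation.threshold_to_network(cm_y, edge_threshold)
    net_x, net_y, effective = _correlation.prune_jointly_isolated(full_x, full_y)
    logger.info(
        "effective taxa: %d of %d; edges X=%d (weight %.3f), Y=%d (weight %.3f)",
        len(effective), len(full_x.taxa),
        net_x.n_edges, net_x.total_weight, net_y.n_edges, net_y.total_weight,
    )

    if not effective:
        logger.warning("no effective taxa at edge_threshold=%s", edge_threshold)
        empty_net = WeightedNetwork([], np.zeros((0, 0)))
        empty_core = _core.CoreSet(focus, [], {}, p_threshold)
        return PipelineResult(
            at_x, at_y, empty_net, empty_net, [],
            _contraction.ContractionMap([]), empty_net, empty_net, empty_core,
            _rewiring.SubnetworkPair([], np.zeros((0, 0)), np.zeros((0, 0))),
            pd.DataFrame(columns=_rewiring.SCORE_COLUMNS),
        )

    # Step 2: cluster, unify, choose representatives, contract
    if skip_contraction:
        cmap = _contraction.identity_contraction_map(effective, taxonomy)
        _contraction.choose_representatives(cmap, at_x, at_y)
        con_x, con_y = net_x, net_y
    else:
        cl_x = _contraction.cluster_nodes(net_x, seed=seed)
        cl_y = _contraction.cluster_nodes(net_y, seed=seed)
        cmap = _contraction.find_similar_groups(taxonomy, cl_x, cl_y)
        _contraction.choose_representatives(cmap, at_x, at_y)
        con_x = _contraction.contract_networks(net_x, cmap, contract_mean)
        con_y = _contraction.contract_networks(net_y, cmap, contract_mean)
        logger.info(
            "contraction: %d effective taxa -> %d groups (%d multi-member)",
            len(effective), len(cmap.groups), cmap.n_multi,
        )

    # Step 3: core selection
    core = _core.select_core(cmap, at_x, at_y, focus=focus, p_threshold=p_threshold)
    if not core.core:
        logger.warning(
            "no representative passed p < %s; outputs will be empty", p_threshold
        )

    # Steps 4-5: core subnetworks and the rewiring score table
    pair = _rewiring.build_core_subnetworks(con_x, con_y, core)
    scores = _rewiring.feature_table(pair, at_x, at_y, core.p_values, core)
    return PipelineResult(
        at_x, at_y, net_x, net_y, effective, cmap, con_x, con_y, core, pair, scores
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """File-based entry point: read inputs, run, write every output.

    Returns the output directory.  Outputs: ``score_table.tsv`` (the main
    result), ``core_bacteria.tsv``, ``unified_groups.tsv``, edge lists and
    GraphML for G_X, G_Y and their |difference| network, and
    ``manifest.json`` recording config and library versions.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    load = _stage("load inputs")(
        lambda: (
            _tables.read_count_table(cfg.counts_x, "X"),
            _tables.read_count_table(cfg.counts_y, "Y"),
            _tables.read_taxonomy(cfg.taxonomy),
        )
    )
    ct_x, ct_y, taxonomy = load()

    result = _stage("pipeline")(run)(
        ct_x,
        ct_y,
        taxonomy,
        focus=cfg.focus,
        edge_threshold=cfg.edge_threshold,
        p_threshold=cfg.p_threshold,
        seed=cfg.seed,
        backend=cfg.backend,
        sparcc_options=_correlation.SparccOptions(iterations=cfg.sparcc_iterations),
        skip_contraction=cfg.skip_contraction,
        contract_mean=cfg.contract_mean,
        unclassified_labels=cfg.unclassified_labels,
        precomputed_x=cfg.precomputed_x,
        precomputed_y=cfg.precomputed_y,
    )

    result.scores.to_csv(out / "score_table.tsv", sep="\t", index=False)
    _core.write_core_tsv(result.core, out / "core_bacteria.tsv")
    _contraction.write_groups_tsv(result.cmap, out / "unified_groups.tsv")
    gx, gy = result.pair.net_x, result.pair.net_y
    gx.write_edgelist(out / "gx_edges.tsv")
    gy.write_edgelist(out / "gy_edges.tsv")
    gx.write_graphml(out / "gx.graphml")
    gy.write_graphml(out / "gy.graphml")
    diff = difference_network(gx, gy)
    diff.write_edgelist(out / "diff_edges.tsv")
    diff.write_graphml(out / "diff.graphml")

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "n_effective_taxa": len(result.effective_taxa),
        "n_groups": len(result.cmap.groups),
        "n_core": len(result.core),
        "n_scored_nodes": len(result.scores),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")

    if cfg.plot and len(result.scores):
        _plot_difference_network(result, out / "diff_network.png")
    return out


def _versions() -> dict[str, str]:
    import networkx
    import scipy

    from . import __version__

    return {
        "qnetdiff": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def _plot_difference_network(result: PipelineResult, path: Path) -> None:
    """Static plot of the |difference| network; node area ∝ rewiring score."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    diff = difference_network(result.pair.net_x, result.pair.net_y)
    g = diff.to_networkx()
    score = result.scores.set_index("taxon")["qnetdiff"]
    smax = max(score.max(), 1e-12)
    sizes = [80 + 1200 * score.get(n, 0.0) / smax for n in g.nodes]
    widths = [2.5 * d["weight"] for _, _, d in g.edges(data=True)]
    pos = nx.circular_layout(g)
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_size=sizes, width=widths, font_size=7,
        node_color="#c6dbef", edge_color="#636363",
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
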