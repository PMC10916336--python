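"""High-level orchestration of the scoring pipeline.

These functions chain the per-stage modules exactly the way the CLI
subcommands do, so library users, tests and the command line all execute
the same code path:

    curate variants -> annotate/impute -> embed the PPI network ->
    concatenate the feature matrix -> cross-validate / train / score.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import annotation_features, classifier, ppi_embedding, variant_io
from .classifier import CVResult
from .ppi_embedding import EmbeddingMatrix, WalkConfig

logger = logging.getLogger(__name__)


def embed_network(edges_path, cfg: dict, roster=None) -> EmbeddingMatrix:
    """Edge list -> binary adjacency -> walk corpus -> skip-gram vectors."""
    edges = ppi_embedding.read_edge_list(edges_path)
    g = ppi_embedding.build_adjacency(edges, cfg["ppi.score_threshold"],
                                      roster=roster)
    logger.info("PPI graph: %d nodes, %d edges", g.number_of_nodes(),
                g.number_of_edges())
    walk_cfg = WalkConfig(p=cfg["embed.p"], q=cfg["embed.q"],
                          walk_length=cfg["embed.walk_length"],
                          walks_per_node=cfg["embed.walks_per_node"],
                          seed=cfg["embed.seed"])
    corpus = ppi_embedding.generate_corpus(g, walk_cfg)
    return ppi_embedding.train_skipgram(
        corpus, k=cfg["embed.dim"], window=cfg["embed.window"],
        epochs=cfg["embed.epochs"], negative_samples=cfg["embed.negative"],
        seed=cfg["embed.seed"], nodes=g.nodes)


def curate(variants_path, cfg: dict, exclusion_path=None) -> variant_io.VariantSet:
    """Read a variant table and apply the rare-variant curation rules."""
    vs = variant_io.read_variant_table(variants_path, dialect="tsv")
    n_read = len(vs)
    vs = variant_io.filter_rare(vs, cfg["curation.af_threshold"])
    logger.info("curation: %d read (%d rows skipped), %d rare survivors",
                n_read, len(vs.skip_report), len(vs))
    if exclusion_path is not None:
        keys = variant_io.read_exclusion_keys(exclusion_path)
        vs = variant_io.apply_exclusion_list(vs, keys)
        logger.info("curation: %d after exclusion list", len(vs))
    return vs


def featurize(vs, annotations_path, emb: EmbeddingMatrix,
              gene_map: dict[str, str], cfg: dict) -> pd.DataFrame:
    """Assemble and impute the full (8 + 17 + k)-column feature matrix."""
    table = annotation_features.read_annotation_table(annotations_path)
    cons, af = annotation_features.assemble_annotation_block(vs, table)
    annot = pd.concat([cons.reset_index(drop=True), af.reset_index(drop=True)],
                      axis=1)
    annot = annotation_features.impute_missing(
        annot, strategy=cfg["impute.strategy"], seed=cfg["impute.seed"],
        knn_k=cfg["impute.knn_k"])
    emb_block = classifier.embedding_block(vs, emb, gene_map)
    cons_i = annot.iloc[:, :cons.shape[1]]
    af_i = annot.iloc[:, cons.shape[1]:]
    return classifier.build_feature_matrix(vs, cons_i, af_i, emb_block)


def run_fixture(fixture_dir, cfg: dict) -> tuple:
    """Curate + embed + featurize a generated fixture directory.

    Returns ``(variant_set, feature_matrix, labels)``.
    """
    d = Path(fixture_dir)
    vs = curate(d / "variants.tsv", cfg)
    gene_map = ppi_embedding.read_gene_map(d / "gene_map.tsv")
    emb = embed_network(d / "edges.tsv", cfg)
    fm = featurize(vs, d / "annotations.tsv", emb, gene_map, cfg)
    return vs, fm, classifier.labels_array(vs)


def cross_validate_fixture(fixture_dir, cfg: dict) -> CVResult:
    """End-to-end tenfold cross-validation on a fixture directory."""
    _, fm, y = run_fixture(fixture_dir, cfg)
    return classifier.cross_validate(
        fm, y, n_trees=cfg["model.n_trees"], seed=cfg["cv.seed"],
        n_folds=cfg["cv.folds"], stratified=cfg["cv.stratified"])
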