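"""Conservation and allele-frequency feature blocks.

Each variant carries 8 evolutionary-conservation features (GERP++,
phastCons/phyloP families, conserved-element summaries) and 17 gnomAD-style
population allele frequencies.  The exact column identities are site- and
annotation-pipeline-dependent, so both blocks are configurable named
schemas; only the counts (8 and 17) are fixed.  Values come from an
ANNOVAR/dbNSFP-style annotation table keyed by (chrom, pos, ref, alt);
missing cells (``.``) are masked and later imputed column-wise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ContractError, ParameterError, SchemaError
from .variant_io import VariantSet

CONSERVATION_SCHEMA = (
    "gerp_rs",
    "phastcons_vertebrate",
    "phastcons_mammalian",
    "phylop_vertebrate",
    "phylop_mammalian",
    "phastcons_element_score",
    "phylop_primate",
    "transcription_conserved_element_flag",
)

AF_SCHEMA = (
    "af_all",
    "af_male",
    "af_female",
    "af_afr",
    "af_sas",
    "af_amr",
    "af_eas",
    "af_nfe",
    "af_fin",
    "af_asj",
    "af_oth",
    # gnomAD v2.1.1-style extra strata filling the remaining slots
    "af_popmax",
    "af_raw",
    "af_controls",
    "af_non_cancer",
    "af_non_neuro",
    "af_non_topmed",
)

KEY_COLUMNS = ("chrom", "pos", "ref", "alt")


def _key_index(df: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_arrays(
        [df["chrom"].astype(str), df["pos"].astype(int),
         df["ref"].astype(str), df["alt"].astype(str)],
        names=KEY_COLUMNS,
    )


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation TSV (``.`` = missing) indexed by variant key."""
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table lacks key column(s): {missing}")
    df.index = _key_index(df)
    return df.drop(columns=list(KEY_COLUMNS))


def assemble_annotation_block(
    vs: VariantSet,
    table: pd.DataFrame,
    conservation_schema=CONSERVATION_SCHEMA,
    af_schema=AF_SCHEMA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join conservation and AF features onto a variant set, row-aligned.

    Returns ``(conservation, af)`` DataFrames with one row per record in
    ``vs`` (same order) and NaN marking missing cells.  Records absent from
    the table get all-missing rows.  AF cells outside [0, 1] are rejected
    and masked missing with a warning — frequencies cannot leave the unit
    interval, so such cells are annotation errors, not data.
    """
    conservation_schema = list(conservation_schema)
    af_schema = list(af_schema)
    if len(conservation_schema) != 8:
        raise SchemaError(f"conservation schema must name 8 features, got {len(conservation_schema)}")
    if len(af_schema) != 17:
        raise SchemaError(f"AF schema must name 17 features, got {len(af_schema)}")
    absent = [c for c in conservation_schema + af_schema if c not in table.columns]
    if absent:
        raise SchemaError(f"annotation table lacks feature column(s): {absent}")

    idx = pd.MultiIndex.from_tuples(vs.keys(), names=KEY_COLUMNS)
    joined = table.reindex(idx)

    cons = joined[conservation_schema].astype(float).copy()
    af = joined[af_schema].astype(float).copy()

    bad = (af < 0) | (af > 1)
    if bad.to_numpy().any():
        n_bad = int(bad.to_numpy().sum())
        warnings.warn(f"{n_bad} allele-frequency cell(s) outside [0,1] masked missing",
                      stacklevel=2)
        af = af.mask(bad)
    return cons, af


def impute_missing(fm: pd.DataFrame, strategy: str = "median", seed: int = 0,
                   knn_k: int = 5) -> pd.DataFrame:
    """Fill missing feature cells column-wise; observed cells are untouched.

    Strategies: ``median`` (default), ``mean`` — per-column statistics of
    the observed values; ``knn`` — mean of the ``knn_k`` nearest rows under
    the nan-Euclidean metric.  A column with no observed value cannot be
    fitted and raises.
    """
    if fm.empty:
        return fm.copy()
    all_missing = [c for c in fm.columns if fm[c].isna().all()]
    if all_missing:
        raise ContractError(f"column(s) entirely missing, cannot impute: {all_missing}")
    if not fm.isna().to_numpy().any():
        return fm.copy()

    from sklearn.impute import KNNImputer, SimpleImputer

    if strategy in ("median", "mean"):
        imp = SimpleImputer(strategy=strategy)
    elif strategy == "knn":
        imp = KNNImputer(n_neighbors=knn_k)
    else:
        raise ParameterError(f"unknown imputation strategy {strategy!r}")
    filled = imp.fit_transform(fm.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=fm.index, columns=fm.columns)
    # imputers may reorder nothing but can drop constant-NaN cols; shape must hold
    if out.shape != fm.shape:
        raise ContractError("imputer changed matrix shape")
    return out
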