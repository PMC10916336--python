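"""Variant table I/O and dataset curation.

Variants are single-nucleotide missense changes identified by the key
``(chrom, pos, ref, alt)`` with 1-based inclusive coordinates (VCF
convention).  Curation follows two rules applied to every benchmark set:

* keep only rare variants — overall gnomAD-style allele frequency below a
  threshold (default 1%); records whose overall AF is missing are removed
  in the same pass;
* when the same variant key appears in several source databases, keep the
  record from the highest-priority source (clinvar > varibench >
  cosmic = varisnp by default).

The on-disk dialect is a UTF-8 TSV with header
``chrom pos ref alt gene label source af_all`` (``.`` or empty = missing);
a VCF 4.x adapter reads gene and label from configurable INFO keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .exceptions import ContractError, ConflictError, ParameterError, SchemaError

NUCLEOTIDES = frozenset("ACGT")
LABELS = frozenset({"disease_related", "neutral", "unknown"})
SOURCES = frozenset({"clinvar", "varibench", "cosmic", "varisnp", "synthetic", "other"})

#: Lower rank = higher priority. cosmic and varisnp deliberately tie.
DEFAULT_PRIORITY = {"clinvar": 0, "varibench": 1, "cosmic": 2, "varisnp": 2,
                    "synthetic": 3, "other": 3}

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "label", "source", "af_all")


@dataclass(frozen=True)
class VariantRecord:
    """One missense SNV with its curation metadata."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    label: str = "unknown"
    source: str = "other"
    af_all: float | None = None

    def __post_init__(self):
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ContractError(f"ref/alt must be single nucleotides, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ContractError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ContractError(f"pos must be >= 1, got {self.pos}")
        if self.label not in LABELS:
            raise ContractError(f"unknown label {self.label!r}")
        if self.source not in SOURCES:
            raise ContractError(f"unknown source {self.source!r}")
        if self.af_all is not None and not 0.0 <= self.af_all <= 1.0:
            raise ContractError(f"af_all outside [0,1]: {self.af_all}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantSet:
    """Ordered collection of unique variant records plus provenance text.

    Uniqueness is enforced on (chrom, pos, ref, alt, source): a raw
    multi-source table may legitimately carry the same variant key from
    two databases before curation; :func:`deduplicate_by_priority`
    restores full key uniqueness.
    """

    records: list[VariantRecord] = field(default_factory=list)
    provenance: str = ""
    skip_report: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        keys = [(*r.key, r.source) for r in self.records]
        if len(keys) != len(set(keys)):
            seen, dups = set(), []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise ContractError(f"duplicate variant records within one set: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [r.key for r in self.records]

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "ref": [r.ref for r in self.records],
                "alt": [r.alt for r in self.records],
                "gene": [r.gene for r in self.records],
                "label": [r.label for r in self.records],
                "source": [r.source for r in self.records],
                "af_all": [r.af_all for r in self.records],
            }
        )


def _parse_af(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in {"", ".", "nan", "NA"}:
        return None
    af = float(s)
    if math.isnan(af):
        return None
    return af


def read_variant_table(path, dialect: str = "tsv", *,
                       gene_info_key: str = "GENE",
                       label_info_key: str = "LABEL",
                       source: str | None = None) -> VariantSet:
    """Read a variant table into a :class:`VariantSet`.

    Rows that are not single-nucleotide substitutions, or that fail record
    validation, are skipped and listed (with their 0-based row index and a
    reason) in ``skip_report`` rather than aborting the read.
    """
    if dialect == "tsv":
        return _read_tsv(path, source)
    if dialect == "vcf":
        return _read_vcf(path, gene_info_key, label_info_key, source)
    raise ParameterError(f"unknown dialect {dialect!r}")


def _read_tsv(path, source_override) -> VariantSet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table {path} lacks required column(s): {missing}")
    records, skipped = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        ref, alt = row.ref.strip().upper(), row.alt.strip().upper()
        if len(ref) != 1 or len(alt) != 1:
            skipped.append((i, f"non-SNV alleles {ref}>{alt}"))
            continue
        try:
            records.append(
                VariantRecord(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=ref,
                    alt=alt,
                    gene=str(row.gene),
                    label=str(row.label),
                    source=source_override or str(row.source),
                    af_all=_parse_af(row.af_all),
                )
            )
        except (ContractError, ValueError) as exc:
            skipped.append((i, str(exc)))
    return VariantSet(records, provenance=f"read_variant_table({path}, tsv)",
                      skip_report=skipped)


def _read_vcf(path, gene_key, label_key, source_override) -> VariantSet:
    from cyvcf2 import VCF

    records, skipped = [], []
    for i, var in enumerate(VCF(str(path))):
        alts = var.ALT or []
        if len(var.REF) != 1 or len(alts) != 1 or len(alts[0]) != 1:
            skipped.append((i, f"non-SNV alleles {var.REF}>{','.join(alts) or '.'}"))
            continue
        try:
            records.append(
                VariantRecord(
                    chrom=str(var.CHROM),
                    pos=int(var.POS),
                    ref=var.REF.upper(),
                    alt=alts[0].upper(),
                    gene=str(var.INFO.get(gene_key, "")),
                    label=str(var.INFO.get(label_key, "unknown")),
                    source=source_override or "other",
                    af_all=_parse_af(var.INFO.get("AF")),
                )
            )
        except (ContractError, ValueError) as exc:
            skipped.append((i, str(exc)))
    return VariantSet(records, provenance=f"read_variant_table({path}, vcf)",
                      skip_report=skipped)


def filter_rare(vs: VariantSet, af_threshold: float = 0.01) -> VariantSet:
    """Keep records with a present overall AF strictly below ``af_threshold``.

    Records with a missing overall AF are removed in the same pass: a record
    whose population frequency is unknown cannot be certified rare.
    Idempotent, order-preserving.
    """
    if not 0.0 < af_threshold <= 1.0:
        raise ParameterError(f"af_threshold must be in (0, 1], got {af_threshold}")
    kept = [r for r in vs.records if r.af_all is not None and r.af_all < af_threshold]
    return VariantSet(
        kept,
        provenance=f"{vs.provenance} | filter_rare(<{af_threshold}, drop missing af_all)",
        skip_report=list(vs.skip_report),
    )


def apply_exclusion_list(vs: VariantSet, keys) -> VariantSet:
    """Drop records whose ``(chrom, pos, ref, alt)`` key is in ``keys``.

    Benchmark construction sometimes requires removing variants already seen
    by other tools' training sets; the caller supplies that key list.
    """
    excl = {(str(c), int(p), r, a) for c, p, r, a in keys}
    kept = [r for r in vs.records if r.key not in excl]
    return VariantSet(kept, provenance=f"{vs.provenance} | exclusion_list({len(excl)} keys)",
                      skip_report=list(vs.skip_report))


def read_exclusion_keys(path) -> list[tuple[str, int, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"exclusion key file lacks column(s): {missing}")
    return [(str(c), int(p), r, a) for c, p, r, a in
            zip(df.chrom, df.pos, df.ref, df.alt)]


def deduplicate_by_priority(sets: list[VariantSet],
                            priority: dict[str, int] | None = None) -> VariantSet:
    """Merge several source-tagged sets, keeping one record per variant key.

    For a key present in multiple sets, the record from the highest-priority
    source survives.  If two sources of *equal* priority both carry the key
    with different labels, that is an unresolvable annotation conflict and a
    :class:`ConflictError` listing the keys is raised.  Output order: records
    of the first input set first (its original order), then novel keys of the
    second, and so on.
    """
    prio = DEFAULT_PRIORITY if priority is None else priority
    best: dict[tuple, VariantRecord] = {}
    order: list[tuple] = []
    conflicts = set()
    for vs in sets:
        for rec in vs.records:
            rank = prio.get(rec.source)
            if rank is None:
                raise ParameterError(f"no priority defined for source {rec.source!r}")
            cur = best.get(rec.key)
            if cur is None:
                best[rec.key] = rec
                order.append(rec.key)
                continue
            cur_rank = prio[cur.source]
            if rank < cur_rank:
                best[rec.key] = rec
            elif rank == cur_rank and rec.label != cur.label:
                conflicts.add(rec.key)
    if conflicts:
        raise ConflictError(sorted(conflicts))
    merged = [best[k] for k in order]
    prov = " + ".join(vs.provenance or "(unnamed)" for vs in sets)
    return VariantSet(merged, provenance=f"dedup_by_priority[{prov}]")


def write_scores(vs: VariantSet, scores, path) -> None:
    """Write per-record pathogenicity scores as a TSV, in input order."""
    scores = list(scores)
    if len(scores) != len(vs):
        raise ContractError(f"{len(vs)} records but {len(scores)} scores")
    for s in scores:
        if not 0.0 <= float(s) <= 1.0:
            raise ContractError(f"score outside [0,1]: {s}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tlabel\tdva_score\n")
        for rec, s in zip(vs.records, scores):
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t"
                     f"{rec.gene}\t{rec.label}\t{float(s):.6f}\n")


def read_scores(path) -> pd.DataFrame:
    """Read a score TSV produced by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "ref", "alt", "gene", "label", "dva_score")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"score table lacks column(s): {missing}")
    return df


def write_variant_table(vs: VariantSet, path) -> None:
    """Write a variant set in the canonical TSV dialect (``.`` = missing AF)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for r in vs.records:
            af = "." if r.af_all is None else f"{r.af_all:.8g}"
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.gene}\t"
                     f"{r.label}\t{r.source}\t{af}\n")
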