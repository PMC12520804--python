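"""Readers and writers for the pipeline's external formats.

Native dialect is TSV: screening records carry columns (conservation index,
cloverleaf numbering, pairing arrows) that have no VCF equivalent.  A
minimal VCF import (chrM, SNVs only) is provided for interoperability, and
FASTA is used for sequence input.  The bundled study variant table loads
through :func:`load_study_table` / :func:`study_records`.

Reports are bit-stable: fixed column order, CI at 1 decimal, carrier
percents at 2, p at printed precision (3 decimals below 0.05, else 2), and
Unicode pairing arrows with an ASCII fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .catalog import Catalog
from .screen import ScreenRecord, screen_variant
from .stats import CarrierCounts, DegenerateTableError, pearson_chi2
from .variants import (
    PairEffect,
    StructuralAnnotation,
    Variant,
    annotate_variant,
)

__all__ = [
    "TableFormatError",
    "ScreenTable",
    "read_variant_table",
    "read_genotype_table",
    "read_clinical_table",
    "read_fasta",
    "read_vcf",
    "load_study_table",
    "study_records",
    "annotation_agreement",
    "recomputed_p",
    "write_report",
    "read_report",
]

REPORT_COLUMNS = [
    "gene",
    "mutation",
    "ci_percent",
    "element",
    "numbering",
    "wc",
    "case_carriers",
    "case_percent",
    "control_carriers",
    "control_percent",
    "p",
    "previously_reported",
    "classification",
    "functional_evidence",
]

_ASCII_ARROWS = {"↑": " created", "↓": " disrupted"}


class TableFormatError(ValueError):
    """A tabular input failed validation; the message names the line."""


def _read_tsv(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableFormatError(f"{path.name}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    # data starts after the header; +2 converts 0-based row index to file line
    df.index = df.index + 2
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant/genotype TSV (columns ``pos``, ``ref``, ``alt``, and
    optionally ``subject_id`` and ``group``).

    Returns a DataFrame with a parsed ``variant`` column of
    :class:`~mttrnascreen.variants.Variant`; malformed rows raise
    :class:`TableFormatError` naming the file line.
    """
    path = Path(path)
    df = _read_tsv(path, {"pos", "ref", "alt"})
    variants = []
    for line, row in df.iterrows():
        try:
            pos = int(row["pos"])
        except ValueError:
            raise TableFormatError(
                f"{path.name}:{line}: non-integer position {row['pos']!r}"
            ) from None
        try:
            variants.append(Variant(position=pos, ref=row["ref"], alt=row["alt"]))
        except ValueError as exc:
            raise TableFormatError(f"{path.name}:{line}: {exc}") from None
        if "group" in df.columns and row["group"] not in ("case", "control", ""):
            raise TableFormatError(
                f"{path.name}:{line}: unknown group label {row['group']!r}"
            )
    out = df.copy()
    out["variant"] = variants
    return out.reset_index(drop=True)


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format genotype TSV (``subject_id``, ``group``,
    ``variant`` label per carried variant)."""
    path = Path(path)
    df = _read_tsv(path, {"subject_id", "group", "variant"})
    for line, row in df.iterrows():
        if row["group"] not in ("case", "control"):
            raise TableFormatError(
                f"{path.name}:{line}: unknown group label {row['group']!r}"
            )
        try:
            Variant.from_label(row["variant"])
        except ValueError as exc:
            raise TableFormatError(f"{path.name}:{line}: {exc}") from None
    return df.reset_index(drop=True)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a per-subject clinical covariate TSV (``subject_id``, ``group``,
    numeric covariate columns)."""
    path = Path(path)
    df = _read_tsv(path, {"subject_id", "group"})
    out = df.reset_index(drop=True)
    for col in out.columns:
        if col in ("subject_id", "group"):
            continue
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load FASTA records as an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_vcf(path: str | Path) -> list[Variant]:
    """Minimal VCF import: chrM/MT contig, 1-based POS, SNVs only.

    Multi-allelic records are split; non-SNV alleles are skipped.  Requires
    pysam.
    """
    import pysam

    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.chrom not in ("chrM", "MT", "chrMT", "M"):
                raise TableFormatError(
                    f"unexpected contig {rec.chrom!r}; expected chrM/MT"
                )
            if rec.ref is None or len(rec.ref) != 1:
                continue
            for alt in rec.alts or ():
                if len(alt) == 1 and alt in "ACGT" and rec.ref in "ACGT":
                    out.append(Variant(position=rec.pos, ref=rec.ref, alt=alt))
    return sorted(out)


# ---------------------------------------------------------------------------
# Bundled study table
# ---------------------------------------------------------------------------


def load_study_table() -> pd.DataFrame:
    """The bundled published screening table (43 variants, printed values)."""
    ref = resources.files("mttrnascreen.data").joinpath("study_variants.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)
    df["variant"] = [Variant.from_label(m) for m in df["mutation"]]
    return df


def recomputed_p(row: pd.Series, n_cases: int = 302, n_controls: int = 589) -> float:
    """Uncorrected Pearson chi-square p for one study-table row's counts.

    Returns NaN for rows with no carriers in either group (degenerate table).
    """
    counts = CarrierCounts(
        a=int(row["case_carriers"]),
        b=n_cases - int(row["case_carriers"]),
        c=int(row["control_carriers"]),
        d=n_controls - int(row["control_carriers"]),
    )
    try:
        return pearson_chi2(counts).p
    except DegenerateTableError:
        return math.nan


def study_records(
    recompute_p: bool = True, n_cases: int = 302, n_controls: int = 589
) -> list[ScreenRecord]:
    """Screen records built from the bundled study table.

    Structural fields (gene, numbering, element, pairing arrow) come from
    the table itself, so this path is independent of the gene catalog; CI is
    the printed value.  With ``recompute_p`` the association p-value is
    recomputed from the printed counts, otherwise the printed p is carried.
    """
    records = []
    for _, row in load_study_table().iterrows():
        wc = str(row["wc"])
        effect = (
            PairEffect.CREATED
            if "↑" in wc
            else PairEffect.DISRUPTED
            if "↓" in wc
            else PairEffect.NONE
        )
        annotation = StructuralAnnotation(
            variant=row["variant"],
            gene=row["gene"],
            trna_position=int(row["numbering"]),
            element=row["element"],
            pair_effect=effect,
            pair_string=wc.rstrip("↑↓"),
            partner=None,
        )
        counts = CarrierCounts(
            a=int(row["case_carriers"]),
            b=n_cases - int(row["case_carriers"]),
            c=int(row["control_carriers"]),
            d=n_controls - int(row["control_carriers"]),
        )
        p = recomputed_p(row, n_cases, n_controls) if recompute_p else float(row["p"])
        records.append(
            screen_variant(
                annotation,
                counts,
                ci_percent=float(row["ci_percent"]),
                p=None if math.isnan(p) else p,
                previously_reported=str(row["previously_reported"]).lower() == "yes",
            )
        )
    return records


def annotation_agreement(catalog: Catalog, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-row comparison of catalog-driven annotation with the study table.

    For each table row, annotates the variant against the catalog and
    reports whether gene, numbering, element, pairing arrow and rendered
    pair string agree with the printed values.  Disagreements are reported,
    never silently dropped: the caller decides what to assert.
    """
    if table is None:
        table = load_study_table()
    rows = []
    for _, row in table.iterrows():
        ann = annotate_variant(catalog, row["variant"])
        wc = str(row["wc"])
        printed_effect = (
            PairEffect.CREATED
            if "↑" in wc
            else PairEffect.DISRUPTED
            if "↓" in wc
            else PairEffect.NONE
        )
        rows.append(
            {
                "mutation": row["mutation"],
                "gene_match": ann.gene == row["gene"],
                "numbering_match": ann.trna_position == int(row["numbering"]),
                "element_match": ann.element == row["element"],
                "arrow_match": ann.pair_effect == printed_effect,
                "pair_string_match": ann.wc_annotation == wc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Screening report
# ---------------------------------------------------------------------------


@dataclass
class ScreenTable:
    """An ordered set of screen records plus run provenance."""

    records: list[ScreenRecord]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.annotation.variant.label for r in self.records]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate variant labels in report: {sorted(dupes)}")
        if not self.provenance:
            from . import __version__

            self.provenance = {"tool": f"mttrnascreen {__version__}"}


def _format_p(p: float | None) -> str:
    if p is None:
        return ""
    return f"{p:.3f}" if p < 0.05 else f"{p:.2f}"


def write_report(table: ScreenTable, path: str | Path, ascii_arrows: bool = False) -> None:
    """Write a bit-stable screening report TSV.

    Fixed column order and rounding (CI one decimal, carrier percents two,
    p at printed precision); provenance in ``#`` header lines.  With
    ``ascii_arrows`` the ↑/↓ glyphs become " created"/" disrupted".
    """
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in sorted(table.provenance.items())]
    lines.append("\t".join(REPORT_COLUMNS))
    for r in table.records:
        wc = r.annotation.wc_annotation
        if ascii_arrows:
            for glyph, word in _ASCII_ARROWS.items():
                wc = wc.replace(glyph, word)
        ci = "" if r.ci_percent is None else f"{r.ci_percent:.1f}"
        lines.append(
            "\t".join(
                [
                    r.annotation.gene,
                    r.annotation.variant.short_label,
                    ci,
                    r.annotation.element,
                    str(r.annotation.trna_position),
                    wc,
                    str(r.counts.a),
                    f"{r.counts.case_percent:.2f}",
                    str(r.counts.c),
                    f"{r.counts.control_percent:.2f}",
                    _format_p(r.p),
                    "Yes" if r.previously_reported else "No",
                    r.classification.value,
                    r.functional_evidence.value,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a screening report back into a DataFrame (round-trips with
    :func:`write_report` at the text level)."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def build_screen_table(
    catalog: Catalog,
    variants: Sequence[Variant],
    counts_by_label: dict[str, CarrierCounts],
    ci_by_label: dict[str, float] | None = None,
    reported_labels: Iterable[str] = (),
    provenance: dict[str, str] | None = None,
) -> ScreenTable:
    """Annotate, test and classify a set of variants into a report table."""
    ci_by_label = ci_by_label or {}
    reported = set(reported_labels)
    records = []
    for v in variants:
        ann = annotate_variant(catalog, v)
        counts = counts_by_label[v.label]
        try:
            p = pearson_chi2(counts).p
        except DegenerateTableError:
            p = None
        records.append(
            screen_variant(
                ann,
                counts,
                ci_percent=ci_by_label.get(v.label),
                p=p,
                previously_reported=v.label in reported,
            )
        )
    return ScreenTable(records=records, provenance=provenance or {})
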