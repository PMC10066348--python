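"""Readers and writers for the pipeline's interchange formats.

The primary interchange format is a TSV with one row per distinct variant
(annotation bundles are too wide for comfortable VCF INFO usage); a VCF
adapter is provided for ingestion convenience. Control summaries travel as
a small TSV (gene, count and/or frequency, N); classification and burden
outputs are TSV, and the audit record is JSON.
"""

from __future__ import annotations

import json
from dataclasses import fields as dc_fields
from typing import Optional, Sequence

import pandas as pd

from .models import AnnotatedVariant, BurdenRow, ClassifiedVariant, ControlSummary

#: Column order of the variant-table TSV. Starred-in-docs optional columns
#: may be empty; everything else is mandatory.
VARIANT_COLUMNS = (
    "variant_id", "gene", "transcript", "consequence",
    "splice_ada", "splice_rf",
    "gnomad_het_count", "gnomad_hom_count", "gnomad_af",
    "local_carrier_count", "local_hom_count",
    "clinvar_status", "clinvar_same_aa_pathogenic", "clinvar_other_aa_change_pathogenic",
    "pext", "gene_z_score", "in_functional_domain", "in_repeat_region",
    "phastcons", "hsf_splice_impact",
    "nmd_predicted_by_position", "known_pathogenic_downstream",
    "splice_frame_disrupted", "pms2_unique_region",
    "lit_case_control_or", "lit_patient_count", "lit_functional", "lit_segregation",
    "in_silico_consensus", "carrier_ids",
)

OPTIONAL_COLUMNS = frozenset({
    "splice_ada", "splice_rf", "gene_z_score", "splice_frame_disrupted",
    "lit_case_control_or", "carrier_ids",
})

_BOOL_FIELDS = frozenset({
    "clinvar_same_aa_pathogenic", "clinvar_other_aa_change_pathogenic",
    "in_functional_domain", "in_repeat_region", "hsf_splice_impact",
    "nmd_predicted_by_position", "known_pathogenic_downstream",
    "splice_frame_disrupted", "pms2_unique_region",
})
_INT_FIELDS = frozenset({
    "gnomad_het_count", "gnomad_hom_count", "local_carrier_count",
    "local_hom_count", "lit_patient_count",
})
_FLOAT_FIELDS = frozenset({
    "splice_ada", "splice_rf", "gnomad_af", "pext", "gene_z_score",
    "phastcons", "lit_case_control_or",
})


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(token: str, row: int, col: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"row {row}: column {col!r}: malformed boolean {token!r}")


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str) -> None:
    extra_cols = sorted({k for v in variants for k in v.extras})
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS + tuple(extra_cols)) + "\n")
        for v in variants:
            row = []
            for col in VARIANT_COLUMNS:
                val = getattr(v, col)
                if col == "carrier_ids":
                    val = ";".join(val)
                row.append(_fmt(val))
            row.extend(_fmt(v.extras.get(c)) for c in extra_cols)
            fh.write("\t".join(row) + "\n")


def read_variant_table(path: str) -> list[AnnotatedVariant]:
    """Parse the variant-table TSV into typed records.

    Unknown columns are preserved per-variant in ``extras``; missing optional
    fields take their documented defaults; a missing mandatory field raises
    with the row and column named.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns
                    and c not in OPTIONAL_COLUMNS]
    if missing_cols:
        raise ValueError(f"variant table is missing column(s): {', '.join(missing_cols)}")
    extra_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]

    variants: list[AnnotatedVariant] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        kwargs = {}
        for col in VARIANT_COLUMNS:
            token = str(rec.get(col, "")).strip()
            if token == "":
                if col in OPTIONAL_COLUMNS:
                    kwargs[col] = () if col == "carrier_ids" else None
                    continue
                raise ValueError(f"row {i}: mandatory column {col!r} is empty")
            if col == "carrier_ids":
                kwargs[col] = tuple(t for t in token.split(";") if t)
            elif col in _BOOL_FIELDS:
                kwargs[col] = _parse_bool(token, i, col)
            elif col in _INT_FIELDS:
                try:
                    kwargs[col] = int(token)
                except ValueError:
                    raise ValueError(
                        f"row {i}: column {col!r}: malformed integer {token!r}") from None
            elif col in _FLOAT_FIELDS or col == "gnomad_af":
                try:
                    kwargs[col] = float(token)
                except ValueError:
                    raise ValueError(
                        f"row {i}: column {col!r}: malformed number {token!r}") from None
            else:
                kwargs[col] = token
        if kwargs["variant_id"] in seen:
            raise ValueError(f"row {i}: duplicate variant_id {kwargs['variant_id']!r}")
        seen.add(kwargs["variant_id"])
        kwargs["extras"] = {c: rec[c] for c in extra_cols if str(rec[c]).strip() != ""}
        variants.append(AnnotatedVariant(**kwargs))
    return variants


# ---------------------------------------------------------------------------
# control summary

def write_control_summary(control: ControlSummary, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcontrol_count\tcontrol_freq_percent\tn_control\n")
        for gene in control.per_gene_count:
            c = control.per_gene_count.get(gene)
            f = control.per_gene_freq_percent.get(gene)
            fh.write(f"{gene}\t{_fmt(c)}\t{_fmt(f)}\t{control.n_individuals}\n")


def read_control_summary(path: str) -> ControlSummary:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "n_control"):
        if col not in df.columns:
            raise ValueError(f"control summary is missing column {col!r}")
    if "control_count" not in df.columns and "control_freq_percent" not in df.columns:
        raise ValueError("control summary needs control_count or control_freq_percent")
    counts: dict[str, Optional[int]] = {}
    freqs: dict[str, Optional[float]] = {}
    n_values = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        gene = rec["gene"].strip()
        n_values.add(int(rec["n_control"]))
        c = str(rec.get("control_count", "")).strip()
        f = str(rec.get("control_freq_percent", "")).strip()
        counts[gene] = int(c) if c else None
        freqs[gene] = float(f) if f else None
    if len(n_values) != 1:
        raise ValueError("control summary has inconsistent n_control values")
    return ControlSummary(n_individuals=n_values.pop(),
                          per_gene_count=counts, per_gene_freq_percent=freqs)


# ---------------------------------------------------------------------------
# outputs

def write_classification_table(classified: Sequence[ClassifiedVariant], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tgene\tcriteria\tpoints\tclassification\n")
        for cv in classified:
            crit = ";".join(c.label for c in cv.criteria)
            fh.write(f"{cv.variant_id}\t{cv.gene}\t{crit}\t{cv.points}\t{cv.classification}\n")


def burden_rows_to_frame(rows: Sequence[BurdenRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene,
        "study_count": r.study_count,
        "study_freq_percent": r.study_freq,
        "control_count": r.control_count,
        "control_freq_percent": r.control_freq,
        "odds_ratio": r.odds_ratio,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "chi2": r.chi2,
        "p_value": r.p_value,
    } for r in rows])


def write_burden_table(rows: Sequence[BurdenRow], path: str) -> None:
    df = burden_rows_to_frame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_burden_json(rows: Sequence[BurdenRow], path: str) -> None:
    df = burden_rows_to_frame(rows)
    records = df.where(df.notna(), None).to_dict("records")
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_audit(audit: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# VCF adapter

_VCF_INFO_FIELDS = tuple(c for c in VARIANT_COLUMNS if c != "variant_id")


def write_vcf(variants: Sequence[AnnotatedVariant], path: str) -> None:
    """Emit the cohort as a plain-text VCF with annotations as INFO keys.

    ``carrier_ids`` are '|'-joined (';' separates INFO keys in VCF).
    """
    chroms = []
    for v in variants:
        chrom = v.variant_id.split(":")[0]
        if chrom not in chroms:
            chroms.append(chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        for name in _VCF_INFO_FIELDS:
            fh.write(f'##INFO=<ID={name.upper()},Number=1,Type=String,'
                     f'Description="{name}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            chrom, pos, ref, alt = v.variant_id.split(":")
            info = []
            for name in _VCF_INFO_FIELDS:
                val = getattr(v, name)
                if name == "carrier_ids":
                    if not val:
                        continue
                    val = "|".join(val)
                elif val is None:
                    continue
                else:
                    val = _fmt(val)
                info.append(f"{name.upper()}={val}")
            fh.write(f"{chrom}\t{pos}\t{v.variant_id}\t{ref}\t{alt}\t.\t.\t"
                     + ";".join(info) + "\n")


def read_vcf(path: str) -> list[AnnotatedVariant]:
    """Ingest a VCF produced by :func:`write_vcf` (or any VCF carrying the
    same INFO keys) into the same records the TSV reader yields."""
    from cyvcf2 import VCF  # optional dependency

    variants: list[AnnotatedVariant] = []
    for i, rec in enumerate(VCF(path), start=1):
        kwargs = {"variant_id": f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"}
        for name in _VCF_INFO_FIELDS:
            raw = rec.INFO.get(name.upper())
            if raw is None:
                if name in OPTIONAL_COLUMNS:
                    kwargs[name] = () if name == "carrier_ids" else None
                    continue
                raise ValueError(f"VCF record {i}: mandatory INFO key "
                                 f"{name.upper()} is missing")
            token = str(raw)
            if name == "carrier_ids":
                kwargs[name] = tuple(t for t in token.split("|") if t)
            elif name in _BOOL_FIELDS:
                kwargs[name] = _parse_bool(token, i, name)
            elif name in _INT_FIELDS:
                kwargs[name] = int(token)
            elif name in _FLOAT_FIELDS or name == "gnomad_af":
                kwargs[name] = float(token)
            else:
                kwargs[name] = token
        variants.append(AnnotatedVariant(**kwargs))
    return variants
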