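"""Readers and writers for ClinVar-style VCFs and annotator output dialects.

Three annotators are supported, each with its own on-disk dialect:

* SnpEff  — pipe-delimited ``ANN`` INFO entries,
* VEP     — pipe-delimited ``CSQ`` INFO entries whose field order comes from
            the VCF header,
* ANNOVAR — tab-delimited multianno tables with ``:``-joined sub-fields.

All parsers map their dialect's missing-value sentinels (``.``, ``""``,
absent field) to ``None`` and never crash on malformed entries: problems are
counted in a :class:`~varconcord.model.ParseStats` and the entry is skipped
or flagged.
"""

from __future__ import annotations

import urllib.parse
from collections.abc import Iterator, Mapping
from pathlib import Path

import pandas as pd
import pysam

from .model import (
    ACCESSION_RE,
    ClinSig,
    ClinVarRecord,
    GenomicVariant,
    ParseStats,
    Tool,
    ToolAnnotation,
    split_accession,
)

# ClinVar's published review-status -> star tiers. The keys are the
# CLNREVSTAT tokens with commas preserved.
DEFAULT_STAR_MAP: dict[str, int] = {
    "practice_guideline": 4,
    "reviewed_by_expert_panel": 3,
    "criteria_provided,_multiple_submitters,_no_conflicts": 2,
    "criteria_provided,_conflicting_interpretations": 1,
    "criteria_provided,_conflicting_classifications": 1,
    "criteria_provided,_single_submitter": 1,
    "no_assertion_criteria_provided": 0,
    "no_assertion_provided": 0,
    "no_classification_provided": 0,
    "no_classification_for_the_single_variant": 0,
}

_CLNSIG_MAP: dict[str, ClinSig] = {
    "pathogenic": ClinSig.P,
    "likely_pathogenic": ClinSig.LP,
    "pathogenic/likely_pathogenic": ClinSig.LP,
    "benign": ClinSig.B,
    "likely_benign": ClinSig.LB,
    "benign/likely_benign": ClinSig.LB,
    "uncertain_significance": ClinSig.VUS,
    "conflicting_interpretations_of_pathogenicity": ClinSig.CONFLICTING,
    "conflicting_classifications_of_pathogenicity": ClinSig.CONFLICTING,
}


def stars_from_review_status(raw: str, star_map: Mapping[str, int]) -> int:
    key = raw.strip().lower()
    if key in star_map:
        return star_map[key]
    if key.startswith("no_assertion") or key.startswith("no_classification"):
        return 0
    if "conflicting" in key:
        return 1
    return 0


def _info_str(value) -> str:
    """Join a pysam INFO value (str or tuple of str) back into one string."""
    if value is None:
        return ""
    if isinstance(value, (tuple, list)):
        return ",".join(str(v) for v in value)
    return str(value)


def _clnsig_from_token(raw: str) -> ClinSig:
    # combined assertions like "Benign|other" carry the class first
    head = raw.split("|")[0].strip().lower()
    return _CLNSIG_MAP.get(head, ClinSig.OTHER)


def _parse_mc(raw: str, flags: list[str], stats: ParseStats) -> list[tuple[str | None, str]]:
    """Parse MC entries of the form ``SO:0001575|splice_donor_variant``.

    ClinVar's MC field carries no transcript accession, so the accession slot
    is None; entries with an unexpected number of ``|`` segments are flagged,
    never merged.
    """
    out: list[tuple[str | None, str]] = []
    for entry in raw.split(","):
        entry = entry.strip()
        if not entry:
            continue
        parts = entry.split("|")
        if len(parts) == 2 and parts[0].startswith("SO:"):
            out.append((None, parts[1]))
        elif len(parts) == 3 and parts[1].startswith("SO:"):
            # extended per-transcript form used by synthetic references
            out.append((parts[0] or None, parts[2]))
        else:
            flags.append(f"malformed_mc:{entry}")
            stats.bump("malformed_mc")
    return out


def read_clinvar_vcf(
    path: str | Path,
    star_map: Mapping[str, int] | None = None,
    stats: ParseStats | None = None,
) -> Iterator[ClinVarRecord]:
    """Stream ClinVarRecords from a ClinVar-dialect VCF.

    Multi-allelic lines are split per ALT. Lines without a usable ALT are
    counted as skipped; unparseable INFO values yield flagged records rather
    than crashes.
    """
    star_map = DEFAULT_STAR_MAP if star_map is None else star_map
    stats = ParseStats() if stats is None else stats
    vcf = pysam.VariantFile(str(path))

    def info_get(rec, key):
        # pysam raises on keys absent from the header; treat those as missing
        try:
            return _info_str(rec.info.get(key))
        except (KeyError, ValueError):
            return ""

    for rec in vcf:
        if not rec.alts:
            stats.bump("skipped_no_alt")
            continue
        clnsig_raw = info_get(rec, "CLNSIG")
        revstat = info_get(rec, "CLNREVSTAT")
        mc_raw = info_get(rec, "MC")
        hgvs_c = info_get(rec, "CLNHGVSC") or None
        hgvs_p = info_get(rec, "CLNHGVSP") or None
        clnhgvs = info_get(rec, "CLNHGVS")
        if hgvs_c is None and ":c." in clnhgvs:
            hgvs_c = clnhgvs
        clinvar_id = None
        if rec.id and rec.id.isdigit():
            clinvar_id = int(rec.id)
        for alt in rec.alts:
            if alt is None or alt == "." or alt.startswith("<"):
                stats.bump("skipped_symbolic_alt")
                continue
            flags: list[str] = []
            mcs = _parse_mc(mc_raw, flags, stats) if mc_raw else []
            if not clnsig_raw:
                flags.append("missing_clnsig")
                stats.bump("missing_clnsig")
            selected = None
            if hgvs_c and ":" in hgvs_c:
                selected = hgvs_c.split(":", 1)[0]
            yield ClinVarRecord(
                variant=GenomicVariant(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    clinvar_id=clinvar_id,
                ),
                clnsig=_clnsig_from_token(clnsig_raw) if clnsig_raw else ClinSig.OTHER,
                review_status_raw=revstat,
                stars=stars_from_review_status(revstat, star_map),
                molecular_consequences=mcs,
                clinvar_hgvs_c=hgvs_c,
                clinvar_hgvs_p=hgvs_p,
                clinvar_selected_transcript=selected,
                flags=flags,
            )


# --- SnpEff ANN ------------------------------------------------------------

# ANN subfield layout (standard): Allele|Annotation|Impact|Gene_Name|Gene_ID|
# Feature_Type|Feature_ID|Biotype|Rank|HGVS.c|HGVS.p|cDNA|CDS|AA|Distance|Errors
ANN_N_FIELDS = 16
_ANN_FEATURE_IDX = 6
_ANN_HGVSC_IDX = 9
_ANN_HGVSP_IDX = 10


def parse_snpeff_ann(
    vcf_record: pysam.VariantRecord, stats: ParseStats | None = None
) -> list[ToolAnnotation]:
    """Parse the ANN INFO field of one VCF record into ToolAnnotations."""
    stats = ParseStats() if stats is None else stats
    ann = vcf_record.info.get("ANN")
    if ann is None:
        return []
    entries = ann if isinstance(ann, (tuple, list)) else [ann]
    alts = [a for a in (vcf_record.alts or []) if a]
    out: list[ToolAnnotation] = []
    for entry in entries:
        parts = str(entry).split("|")
        if len(parts) < 11:
            stats.bump("malformed_ann_entry")
            continue
        allele = parts[0]
        alt = allele if allele in alts else (alts[0] if alts else allele)
        acc_raw = parts[_ANN_FEATURE_IDX]
        if not ACCESSION_RE.match(acc_raw):
            stats.bump("rejected_accession")
            continue
        accession, version = split_accession(acc_raw)
        consequences = [t for t in parts[1].split("&") if t]
        hgvs_c = parts[_ANN_HGVSC_IDX] or None
        hgvs_p = parts[_ANN_HGVSP_IDX] or None
        try:
            out.append(
                ToolAnnotation(
                    tool=Tool.SNPEFF,
                    variant=GenomicVariant(
                        vcf_record.chrom, vcf_record.pos, vcf_record.ref, alt
                    ),
                    transcript_accession=accession,
                    transcript_version=version,
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                    raw_consequences=consequences,
                )
            )
        except ValueError:
            stats.bump("malformed_ann_entry")
    return out


def format_snpeff_ann(ann: ToolAnnotation) -> str:
    """Serialize one annotation back to an ANN entry (round-trip inverse)."""
    fields = [""] * ANN_N_FIELDS
    fields[0] = ann.variant.alt
    fields[1] = "&".join(ann.raw_consequences)
    fields[2] = "MODIFIER"
    fields[3] = "GENE"
    fields[4] = "GENE"
    fields[5] = "transcript"
    fields[_ANN_FEATURE_IDX] = ann.versioned_accession
    fields[7] = "protein_coding"
    fields[_ANN_HGVSC_IDX] = ann.hgvs_c or ""
    fields[_ANN_HGVSP_IDX] = ann.hgvs_p or ""
    return "|".join(fields)


# --- VEP CSQ ---------------------------------------------------------------

DEFAULT_CSQ_ORDER = [
    "Allele", "Consequence", "IMPACT", "SYMBOL", "Gene", "Feature_type",
    "Feature", "BIOTYPE", "HGVSc", "HGVSp",
]


def csq_field_order_from_header(vcf: pysam.VariantFile) -> list[str]:
    """Extract the CSQ subfield order from the header Description line."""
    rec = vcf.header.info.get("CSQ")
    if rec is None or not rec.description or "Format:" not in rec.description:
        raise ValueError("VCF header lacks a CSQ Description with a Format clause")
    return rec.description.split("Format:", 1)[1].strip().strip('"').split("|")


def parse_vep_csq(
    vcf_record: pysam.VariantRecord,
    csq_field_order: list[str],
    stats: ParseStats | None = None,
) -> list[ToolAnnotation]:
    """Parse the CSQ INFO field using the header-declared field order."""
    stats = ParseStats() if stats is None else stats
    csq = vcf_record.info.get("CSQ")
    if csq is None:
        return []
    entries = csq if isinstance(csq, (tuple, list)) else [csq]
    alts = [a for a in (vcf_record.alts or []) if a]
    out: list[ToolAnnotation] = []
    for entry in entries:
        parts = str(entry).split("|")
        if len(parts) != len(csq_field_order):
            stats.bump("csq_field_count_mismatch")
            continue
        d = dict(zip(csq_field_order, parts))
        acc_raw = d.get("Feature", "")
        if not ACCESSION_RE.match(acc_raw):
            stats.bump("rejected_accession")
            continue
        accession, version = split_accession(acc_raw)
        hgvs_c = d.get("HGVSc") or None
        hgvs_p = d.get("HGVSp") or None
        if hgvs_p:
            hgvs_p = urllib.parse.unquote(hgvs_p)
        protein_acc = None
        if hgvs_p and ":" in hgvs_p:
            protein_acc = hgvs_p.split(":", 1)[0]
        allele = d.get("Allele", "")
        alt = allele if allele in alts else (alts[0] if alts else allele)
        consequences = [t for t in d.get("Consequence", "").split("&") if t]
        try:
            out.append(
                ToolAnnotation(
                    tool=Tool.VEP,
                    variant=GenomicVariant(
                        vcf_record.chrom, vcf_record.pos, vcf_record.ref, alt
                    ),
                    transcript_accession=accession,
                    transcript_version=version,
                    protein_accession=protein_acc,
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                    raw_consequences=consequences,
                )
            )
        except ValueError:
            stats.bump("malformed_csq_entry")
    return out


def format_vep_csq(ann: ToolAnnotation, csq_field_order: list[str] | None = None) -> str:
    """Serialize one annotation back to a CSQ entry (round-trip inverse)."""
    order = csq_field_order or DEFAULT_CSQ_ORDER
    hgvs_p = ann.hgvs_p or ""
    hgvs_p = hgvs_p.replace("=", "%3D")
    d = {
        "Allele": ann.variant.alt,
        "Consequence": "&".join(ann.raw_consequences),
        "Feature": ann.versioned_accession,
        "Feature_type": "Transcript",
        "HGVSc": ann.hgvs_c or "",
        "HGVSp": hgvs_p,
    }
    return "|".join(d.get(name, "") for name in order)


# --- ANNOVAR multianno tables ----------------------------------------------

DEFAULT_ANNOVAR_COLUMNS = {
    "chrom": "Chr",
    "pos": "Start",
    "ref": "Ref",
    "alt": "Alt",
    "func": "Func.refGene",
    "exonic_func": "ExonicFunc.refGene",
    "gene_detail": "GeneDetail.refGene",
    "aa_change": "AAChange.refGene",
}


def _parse_annovar_entry(entry: str) -> tuple[str | None, str | None, str | None]:
    """Split ``GENE:NM_x:exonN:c.x:p.x`` into (accession, hgvs_c, hgvs_p)."""
    accession = hgvs_c = hgvs_p = None
    for token in entry.split(":"):
        if ACCESSION_RE.match(token):
            accession, _ = split_accession(token)  # ANNOVAR is versionless anyway
        elif token.startswith("c."):
            hgvs_c = token
        elif token.startswith("p."):
            hgvs_p = token
    return accession, hgvs_c, hgvs_p


def parse_annovar_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    stats: ParseStats | None = None,
) -> list[ToolAnnotation]:
    """Parse an ANNOVAR tab-delimited multianno table.

    One ToolAnnotation per transcript sub-entry in the AAChange (exonic) or
    GeneDetail (non-exonic) cell. Version and protein accession are always
    absent, as in ANNOVAR's own output.
    """
    cols = dict(DEFAULT_ANNOVAR_COLUMNS)
    if column_map:
        cols.update(column_map)
    stats = ParseStats() if stats is None else stats
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [cols["chrom"], cols["pos"], cols["ref"], cols["alt"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ANNOVAR table missing required columns: {missing}")
    out: list[ToolAnnotation] = []
    for _, row in df.iterrows():
        variant = GenomicVariant(
            chrom=str(row[cols["chrom"]]),
            pos=int(row[cols["pos"]]),
            ref=str(row[cols["ref"]]),
            alt=str(row[cols["alt"]]),
        )
        exonic_func = row.get(cols["exonic_func"], ".")
        func = row.get(cols["func"], ".")
        found = False
        # exonic entries: comma-separated AAChange; others: ;-separated GeneDetail
        for cell, sep, cons in (
            (row.get(cols["aa_change"], "."), ",", exonic_func),
            (row.get(cols["gene_detail"], "."), ";", func),
        ):
            if cell in (".", "", "UNKNOWN"):
                continue
            for entry in str(cell).split(sep):
                accession, hgvs_c, hgvs_p = _parse_annovar_entry(entry)
                if accession is None:
                    stats.bump("rejected_accession")
                    continue
                consequences = [cons] if cons not in (".", "") else []
                try:
                    out.append(
                        ToolAnnotation(
                            tool=Tool.ANNOVAR,
                            variant=variant,
                            transcript_accession=accession,
                            transcript_version=None,
                            hgvs_c=hgvs_c,
                            hgvs_p=hgvs_p,
                            raw_consequences=consequences,
                        )
                    )
                    found = True
                except ValueError:
                    stats.bump("malformed_annovar_entry")
        if not found:
            stats.bump("missing_annotation")
    return out


def format_annovar_entry(ann: ToolAnnotation, gene: str = "GENE") -> str:
    """Serialize one annotation to an AAChange-style sub-entry."""
    tokens = [gene, ann.transcript_accession, "exon1"]
    if ann.hgvs_c:
        tokens.append(ann.hgvs_c)
    if ann.hgvs_p:
        tokens.append(ann.hgvs_p)
    return ":".join(tokens)


# --- normalized annotation table -------------------------------------------

TABLE_COLUMNS = [
    "tool", "chrom", "pos", "ref", "alt",
    "accession", "version", "hgvs_c", "hgvs_p", "consequences",
]


def annotations_to_frame(annotations: list[ToolAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "tool": a.tool.value,
            "chrom": a.variant.chrom,
            "pos": a.variant.pos,
            "ref": a.variant.ref,
            "alt": a.variant.alt,
            "accession": a.transcript_accession,
            "version": "" if a.transcript_version is None else a.transcript_version,
            "hgvs_c": a.hgvs_c or "",
            "hgvs_p": a.hgvs_p or "",
            "consequences": "&".join(a.raw_consequences),
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_annotation_table(annotations: list[ToolAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> list[ToolAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            ToolAnnotation(
                tool=Tool(r["tool"]),
                variant=GenomicVariant(r["chrom"], int(r["pos"]), r["ref"], r["alt"]),
                transcript_accession=r["accession"],
                transcript_version=int(r["version"]) if r["version"] else None,
                hgvs_c=r["hgvs_c"] or None,
                hgvs_p=r["hgvs_p"] or None,
                raw_consequences=[t for t in r["consequences"].split("&") if t],
            )
        )
    return out
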