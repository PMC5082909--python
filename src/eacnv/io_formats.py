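"""Readers and writers for every text format the pipeline touches.

Dialects
--------
* ``pennstyle`` CNV calls: whitespace-delimited records of the form::

      chr8:83573868-83964230 numsnp=245 length=390,363 state5,cn=3 C12 \
          startsnp=rs100 endsnp=rs200 conf=52.4

* ``partitionstyle`` CNV calls: a tab-delimited table with header columns
  (Sample ID, Chr, Start, End, Value, Confidence, #SNPs).

Coordinates are converted to the package-wide 1-based inclusive
convention on read; BED input (0-based half-open) is shifted at this
boundary and nowhere else.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .intervals import GenomicInterval, normalize_chrom, size_kb
from .models import (
    BOTH,
    GAIN,
    LOSS,
    CandidateCnv,
    CnvCall,
    ProbeRecord,
    ReferenceSet,
    SequenceVariant,
    TranscriptRecord,
)

__all__ = [
    "read_cnv_calls",
    "write_cnv_calls",
    "read_probe_table",
    "write_probe_table",
    "read_transcript_annotation",
    "write_transcript_bed",
    "read_reference_cnv_set",
    "write_reference_cnv_set",
    "read_gene_set_library",
    "write_gene_set_library",
    "read_variant_table",
    "write_variant_table",
    "read_symbol_list",
    "write_symbol_list",
    "write_candidate_report",
    "read_candidate_report",
    "read_demographics",
]

PathLike = Union[str, Path]

_PENN_LOCUS = re.compile(r"^(?:chr)?([\w]+):([\d,]+)-([\d,]+)$")
_PENN_STATE = re.compile(r"^state(\d+),cn=(\d+)$")

MISSING = "-"


def _int(s: str) -> int:
    return int(s.replace(",", ""))


# ---------------------------------------------------------------------------
# CNV caller output


def read_cnv_calls(path: PathLike, dialect: str) -> list[CnvCall]:
    """Parse a caller output file into :class:`CnvCall` records.

    Parameters
    ----------
    path : path
        Input file.
    dialect : {"pennstyle", "partitionstyle"}
        Which caller's output layout to expect.
    """
    if dialect == "pennstyle":
        return _read_pennstyle(path)
    if dialect == "partitionstyle":
        return _read_partitionstyle(path)
    raise ValueError(f"unknown CNV call dialect: {dialect!r}")


def _read_pennstyle(path: PathLike) -> list[CnvCall]:
    calls: list[CnvCall] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            try:
                m = _PENN_LOCUS.match(tokens[0])
                chrom = normalize_chrom(m.group(1))
                start, end = _int(m.group(2)), _int(m.group(3))
                fields: dict[str, str] = {}
                copy_number = None
                sample = None
                for tok in tokens[1:]:
                    sm = _PENN_STATE.match(tok)
                    if sm:
                        copy_number = int(sm.group(2))
                        fields["state"] = sm.group(1)
                    elif "=" in tok:
                        k, v = tok.split("=", 1)
                        fields[k] = v
                    elif sample is None:
                        sample = tok
                calls.append(
                    CnvCall(
                        sample=sample,
                        interval=GenomicInterval(chrom, start, end),
                        copy_number=copy_number,
                        n_probes=_int(fields["numsnp"]),
                        confidence=float(fields.get("conf", "0")),
                        caller="pennstyle",
                        annotations={
                            k: v
                            for k, v in fields.items()
                            if k in ("startsnp", "endsnp", "state", "length")
                        },
                    )
                )
            except (AttributeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: unparseable pennstyle record at line {lineno}: "
                    f"{line!r}"
                ) from exc
    return calls


_PARTITION_ALIASES = {
    "sample": ("sample id", "sample", "sampleid"),
    "chrom": ("chr", "chromosome", "chrom"),
    "start": ("start", "start position"),
    "end": ("end", "end position"),
    "copy_number": ("value", "cnv value", "copy number", "cn"),
    "confidence": ("confidence", "cnv confidence", "conf"),
    "n_probes": ("#snps", "num snps", "numsnp", "n probes"),
}


def _read_partitionstyle(path: PathLike) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower().strip(): c for c in df.columns}
    cols: dict[str, str] = {}
    for key, aliases in _PARTITION_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                cols[key] = lower[alias]
                break
        else:
            raise ValueError(
                f"{path}: partitionstyle table lacks a '{aliases[0]}' column"
            )
    calls = []
    for idx, row in df.iterrows():
        try:
            calls.append(
                CnvCall(
                    sample=str(row[cols["sample"]]),
                    interval=GenomicInterval(
                        normalize_chrom(row[cols["chrom"]]),
                        _int(row[cols["start"]]),
                        _int(row[cols["end"]]),
                    ),
                    copy_number=int(float(row[cols["copy_number"]])),
                    n_probes=_int(row[cols["n_probes"]]),
                    confidence=float(row[cols["confidence"]]),
                    caller="partitionstyle",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: unparseable partitionstyle record at line {idx + 2}"
            ) from exc
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: PathLike, dialect: str) -> None:
    """Emit calls in one of the two caller dialects (inverse of reader)."""
    calls = list(calls)
    if dialect == "pennstyle":
        with open(path, "w", encoding="utf-8") as fh:
            for c in calls:
                iv = c.interval
                state = c.annotations.get("state", str(c.copy_number + 1))
                startsnp = c.annotations.get("startsnp", f"rs{iv.start}")
                endsnp = c.annotations.get("endsnp", f"rs{iv.end}")
                fh.write(
                    f"chr{iv.chrom}:{iv.start}-{iv.end}\t"
                    f"numsnp={c.n_probes}\tlength={iv.size_bp:,}\t"
                    f"state{state},cn={c.copy_number}\t{c.sample}\t"
                    f"startsnp={startsnp}\tendsnp={endsnp}\t"
                    f"conf={c.confidence:g}\n"
                )
    elif dialect == "partitionstyle":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["Sample ID", "Chr", "Start", "End", "Value", "Confidence", "#SNPs"]
            )
            for c in calls:
                w.writerow(
                    [
                        c.sample,
                        c.interval.chrom,
                        c.interval.start,
                        c.interval.end,
                        c.copy_number,
                        f"{c.confidence:g}",
                        c.n_probes,
                    ]
                )
    else:
        raise ValueError(f"unknown CNV call dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Probe tables (marker, chrom, position, genotype, BAF, LRR)


def read_probe_table(path: PathLike) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    probes = [
        ProbeRecord(
            marker=str(r.marker),
            chrom=normalize_chrom(r.chrom),
            position=int(r.position),
            genotype=str(r.genotype),
            baf=float(r.baf),
            lrr=float(r.lrr),
        )
        for r in df.itertuples()
    ]
    return probes


def write_probe_table(probes: Iterable[ProbeRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker", "chrom", "position", "genotype", "baf", "lrr"])
        for p in probes:
            w.writerow(
                [p.marker, p.chrom, p.position, p.genotype, f"{p.baf:.4f}", f"{p.lrr:.4f}"]
            )


# ---------------------------------------------------------------------------
# Transcript annotation (BED4 0-based half-open, or GTF 1-based inclusive)


def read_transcript_annotation(path: PathLike, fmt: str = "BED") -> list[TranscriptRecord]:
    """Read transcripts from BED4 or GTF into 1-based inclusive records."""
    fmt = fmt.upper()
    records: list[TranscriptRecord] = []
    if fmt == "BED":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}: BED line {lineno} has <4 columns")
                chrom = normalize_chrom(parts[0])
                start0, end0 = int(parts[1]), int(parts[2])
                if end0 <= start0:
                    raise ValueError(
                        f"{path}: BED line {lineno}: end {end0} <= start {start0}"
                    )
                biotype = parts[4] if len(parts) > 4 else "protein_coding"
                records.append(
                    TranscriptRecord(
                        gene=parts[3],
                        interval=GenomicInterval(chrom, start0 + 1, end0),
                        biotype=biotype,
                    )
                )
    elif fmt == "GTF":
        attr_re = re.compile(r'(\w+) "([^"]*)"')
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}: GTF line {lineno} has <9 columns")
                if parts[2] != "transcript":
                    continue
                attrs = dict(attr_re.findall(parts[8]))
                start, end = int(parts[3]), int(parts[4])
                if end < start:
                    raise ValueError(
                        f"{path}: GTF line {lineno}: end {end} < start {start}"
                    )
                records.append(
                    TranscriptRecord(
                        gene=attrs.get("gene_name", attrs.get("gene_id", "")),
                        interval=GenomicInterval(normalize_chrom(parts[0]), start, end),
                        biotype=attrs.get(
                            "transcript_biotype",
                            attrs.get("transcript_type", "protein_coding"),
                        ),
                        transcript_id=attrs.get("transcript_id", ""),
                    )
                )
    else:
        raise ValueError(f"unknown transcript annotation format: {fmt!r}")
    return records


def write_transcript_bed(records: Iterable[TranscriptRecord], path: PathLike) -> None:
    """Write transcripts as BED4 (+biotype column 5), 0-based half-open."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in records:
            iv = t.interval
            fh.write(f"chr{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{t.gene}\t{t.biotype}\n")


# ---------------------------------------------------------------------------
# Reference CNV interval sets


_VALID_TYPES = {LOSS, GAIN, BOTH}


def read_reference_cnv_set(path: PathLike, name: Optional[str] = None) -> ReferenceSet:
    """Read a tab-delimited reference set (chrom, start, end, type)."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.lower().startswith("chrom"):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: reference line {lineno} has <4 columns")
            cnv_type = parts[3].strip().lower()
            if cnv_type not in _VALID_TYPES:
                raise ValueError(
                    f"{path}: line {lineno}: unknown CNV type {parts[3]!r} "
                    f"(expected loss/gain/both)"
                )
            entries.append(
                (
                    GenomicInterval(normalize_chrom(parts[0]), int(parts[1]), int(parts[2])),
                    cnv_type,
                )
            )
    return ReferenceSet(name=name or Path(path).stem, entries=entries)


def write_reference_cnv_set(ref: ReferenceSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\ttype\n")
        for iv, t in ref.entries:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t}\n")


# ---------------------------------------------------------------------------
# Gene set libraries (GMT) and plain symbol lists


def read_gene_set_library(path: PathLike) -> dict[str, frozenset]:
    """Read a GMT file into {set name: frozenset of uppercase symbols}."""
    library: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: GMT line {lineno} has <2 columns")
            name = parts[0]
            if name in library:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            members = frozenset(s.strip().upper() for s in parts[2:] if s.strip())
            library[name] = members
    return library


def write_gene_set_library(library: dict[str, Iterable[str]], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(library):
            members = sorted(set(s.upper() for s in library[name]))
            fh.write("\t".join([name, ""] + members) + "\n")


def read_symbol_list(path: PathLike) -> frozenset:
    """Plain text symbol list, one symbol per line, uppercased."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip().upper() for line in fh if line.strip() and not line.startswith("#")
        )


def write_symbol_list(symbols: Iterable[str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(set(str(x).upper() for x in symbols)):
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# Sequence variant tables (flat TSV or VCF)

_VARIANT_COLS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "ref_reads",
    "alt_reads",
    "population_af",
    "tier",
    "impact_flag",
    "zygosity",
]


def read_variant_table(path: PathLike, fmt: str = "TSV") -> list[SequenceVariant]:
    """Read variants from a flat TSV or a VCF with AD-style depths.

    For VCF input the gene symbol, tier, impact flag and population
    frequency are taken from INFO keys GENE, TIER, IMPACT and AF_POP
    when present.
    """
    fmt = fmt.upper()
    if fmt == "VCF":
        return _read_vcf(path)
    if fmt != "TSV":
        raise ValueError(f"unknown variant format: {fmt!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    variants = []
    for r in df.itertuples():
        af = getattr(r, "population_af", None)
        af = None if af is None or pd.isna(af) or af == MISSING else float(af)
        variants.append(
            SequenceVariant(
                sample=str(r.sample),
                chrom=normalize_chrom(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                gene=str(r.gene),
                ref_reads=int(r.ref_reads),
                alt_reads=int(r.alt_reads),
                population_af=af,
                tier=str(getattr(r, "tier", "candidate_gene")),
                impact_flag=str(getattr(r, "impact_flag", "False")).lower()
                in ("true", "1", "yes"),
                zygosity_call=str(getattr(r, "zygosity", "het")),
            )
        )
    return variants


def _read_vcf(path: PathLike) -> list[SequenceVariant]:
    variants = []
    with open(path, encoding="utf-8") as fh:
        samples: list[str] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10 or not samples:
                raise ValueError(f"{path}: VCF line {lineno}: no sample columns")
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in parts[7].split(";")
                if kv
            )
            fmt_keys = parts[8].split(":")
            for sample, sample_field in zip(samples, parts[9:]):
                values = dict(zip(fmt_keys, sample_field.split(":")))
                gt = values.get("GT", "./.")
                if gt in ("./.", "0/0", "0|0"):
                    continue
                ad = values.get("AD", "")
                try:
                    ref_reads, alt_reads = (int(x) for x in ad.split(",")[:2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: VCF line {lineno}: missing or malformed AD field"
                    ) from exc
                af = info.get("AF_POP")
                variants.append(
                    SequenceVariant(
                        sample=sample,
                        chrom=normalize_chrom(parts[0]),
                        pos=int(parts[1]),
                        ref=parts[3],
                        alt=parts[4],
                        gene=info.get("GENE", ""),
                        ref_reads=ref_reads,
                        alt_reads=alt_reads,
                        population_af=float(af) if af not in (None, ".", "") else None,
                        tier=info.get("TIER", "candidate_gene"),
                        impact_flag=info.get("IMPACT", "") in ("1", "true", "HIGH"),
                        zygosity_call="hom" if gt in ("1/1", "1|1") else "het",
                    )
                )
    return variants


def write_variant_table(variants: Iterable[SequenceVariant], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VARIANT_COLS)
        for v in variants:
            w.writerow(
                [
                    v.sample,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    v.ref_reads,
                    v.alt_reads,
                    MISSING if v.population_af is None else f"{v.population_af:g}",
                    v.tier,
                    v.impact_flag,
                    v.zygosity_call,
                ]
            )


# ---------------------------------------------------------------------------
# Candidate CNV report (published-table schema)

_REPORT_COLS = [
    "CNV #",
    "Study ID",
    "Type",
    "CN",
    "Sex",
    "Locus",
    "Chrom",
    "Start",
    "End",
    "~Size (Kb)",
    "Probes",
    "Confidence",
    "Caller",
    "Region",
    "Transcripts",
    "Candidate Genes",
    "Recurrent",
    "Cases Sharing",
    "Review",
    "Overlap Profile",
]


def _type_label(c: CandidateCnv) -> str:
    base = "Dupl" if c.cnv_type == "gain" else (
        "Het Del" if c.call.copy_number == 1 else "Del"
    )
    if c.call.is_sex_chrom:
        sex = c.call.annotations.get("sex", "?")
        return f"{base} ({c.call.copy_number},{sex})"
    return base


def write_candidate_report(candidates: Iterable[CandidateCnv], path: PathLike) -> None:
    """Write the candidate-CNV table (one row per carrying case).

    Recurrent CNVs appear as multiple rows sharing a CNV identifier.
    Empty annotation fields print ``-``. Rows are ordered by
    (chromosome, start, sample) for determinism.
    """
    def chrom_key(c: CandidateCnv):
        ch = c.interval.chrom
        return (0, int(ch)) if ch.isdigit() else (1, ord(ch[0]))

    rows = sorted(candidates, key=lambda c: (chrom_key(c), c.interval.start, c.sample))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_REPORT_COLS)
        for c in rows:
            profile = ";".join(
                f"{k}:{v:.6g}" for k, v in sorted(c.overlap_profile.items())
            )
            w.writerow(
                [
                    c.cnv_id if c.cnv_id is not None else MISSING,
                    c.sample,
                    _type_label(c),
                    c.call.copy_number,
                    c.call.annotations.get("sex", MISSING),
                    c.locus or MISSING,
                    c.interval.chrom,
                    c.interval.start,
                    c.interval.end,
                    size_kb(c.interval),
                    c.call.n_probes,
                    f"{c.call.confidence:g}",
                    c.call.caller,
                    c.call.region_class,
                    ";".join(c.transcripts) if c.transcripts else MISSING,
                    ";".join(c.candidate_gene_hits) if c.candidate_gene_hits else MISSING,
                    c.recurrent,
                    c.n_cases_sharing,
                    c.review_flag,
                    profile or MISSING,
                ]
            )


def read_candidate_report(path: PathLike) -> list[CandidateCnv]:
    """Inverse of :func:`write_candidate_report` (lossless round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        row = dict(zip(_REPORT_COLS, r))
        sex = row["Sex"]
        annotations = {} if sex == MISSING else {"sex": sex}
        interval = GenomicInterval(row["Chrom"], int(row["Start"]), int(row["End"]))
        copy_number = int(row["CN"])
        expected = 2
        if row["Region"] in ("X_nonPAR", "Y_nonPAR"):
            # infer ploidy back from type label direction
            expected = 1 if (row["Region"] == "Y_nonPAR" or sex == "M") else 2
        call = CnvCall(
            sample=row["Study ID"],
            interval=interval,
            copy_number=copy_number,
            n_probes=int(row["Probes"]),
            confidence=float(row["Confidence"]),
            caller=row["Caller"],
            region_class=row["Region"],
            expected_ploidy=expected,
            annotations=annotations,
        )
        profile = {}
        if row["Overlap Profile"] != MISSING:
            for item in row["Overlap Profile"].split(";"):
                k, v = item.rsplit(":", 1)
                profile[k] = float(v)
        out.append(
            CandidateCnv(
                call=call,
                overlap_profile=profile,
                transcripts=[] if row["Transcripts"] == MISSING else row["Transcripts"].split(";"),
                candidate_gene_hits=[]
                if row["Candidate Genes"] == MISSING
                else row["Candidate Genes"].split(";"),
                recurrent=row["Recurrent"] == "True",
                n_cases_sharing=int(row["Cases Sharing"]),
                cnv_id=None if row["CNV #"] == MISSING else int(row["CNV #"]),
                review_flag=row["Review"],
                locus="" if row["Locus"] == MISSING else row["Locus"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Demographics tables (characteristic, category, population_count, case_count)


def read_demographics(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"characteristic", "category", "population_count", "case_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: demographics table lacks columns {sorted(missing)}")
    return df
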