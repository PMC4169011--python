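"""Readers and writers for the on-disk formats.

Formats handled: tab-delimited methylome tables (chrom, pos, meth, total),
BED4/BED6 signal sites, BED12 or minimal GTF gene models, TSV FPKM matrices,
TSV genome layouts, BED-with-label region tables and YAML configs. Everything
is normalised to 0-based half-open coordinates on the way in; BED is 0-based
by definition, the methylome table's base is declared by the caller.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import FormatError, GeneModel, GenomeLayout, Region, SignalSite

logger = logging.getLogger(__name__)

METHYLOME_COLUMNS = ["chrom", "pos", "meth", "total"]


# ---------------------------------------------------------------------------
# methylome tables
# ---------------------------------------------------------------------------

def read_methylome(
    path: str | Path,
    one_based: bool = False,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Read a per-CpG count table into a sorted DataFrame.

    Parameters
    ----------
    path
        Tab-delimited file with columns chrom, position, methylated-read
        count, total-read count. Lines starting with ``#`` are ignored.
    one_based
        Declare the file's position convention; positions are shifted to
        0-based when True.
    layout
        When given, records on chromosomes absent from the layout (or beyond
        the chromosome end) are dropped with a warning.

    Raises
    ------
    FormatError
        On malformed lines or a methylated count exceeding the total; the
        message carries the 1-based line number.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                pos = int(fields[1])
                meth = int(fields[2])
                total = int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if meth < 0 or total < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if meth > total:
                raise FormatError(
                    f"{path}:{lineno}: methylated count {meth} exceeds total {total}"
                )
            if one_based:
                pos -= 1
            if pos < 0:
                raise FormatError(f"{path}:{lineno}: negative position after normalisation")
            rows.append((chrom, pos, meth, total))

    df = pd.DataFrame(rows, columns=METHYLOME_COLUMNS)
    n_in = len(df)
    if layout is not None and n_in:
        known = df["chrom"].isin(layout.chrom_names)
        if not known.all():
            bad = df.loc[~known, "chrom"].unique()
            logger.warning(
                "%s: dropping %d records on unknown chromosomes %s",
                path, int((~known).sum()), list(bad),
            )
            df = df[known]
        lengths = df["chrom"].map(layout.as_dict())
        inside = df["pos"] < lengths
        if not inside.all():
            logger.warning(
                "%s: dropping %d records beyond chromosome ends", path, int((~inside).sum())
            )
            df = df[inside]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    logger.info("read_methylome(%s): %d lines in, %d records kept", path, n_in, len(df))
    return df


def write_methylome(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=METHYLOME_COLUMNS)


# ---------------------------------------------------------------------------
# interval formats: BED sites, BED12 / minimal GTF genes
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, kind: str) -> list:
    """Read signal sites (``kind='sites'``) or gene models (``kind='genes'``).

    Sites come from BED4+ (name column used as the mark label). Genes come
    from BED6/BED12 (strand in column 6) or from a minimal GTF whose lines
    have feature type ``gene`` and a ``gene_id`` attribute. For minus-strand
    genes the transcription start is the BED end coordinate.
    """
    path = Path(path)
    if kind not in ("sites", "genes"):
        raise ValueError(f"kind must be 'sites' or 'genes', got {kind!r}")
    if path.suffix.lower() in (".gtf", ".gff"):
        if kind != "genes":
            raise FormatError("GTF input is only supported for gene models")
        return _read_gtf_genes(path)
    return _read_bed(path, kind)


def _read_bed(path: Path, kind: str) -> list:
    out: list = []
    n_bad = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                logger.warning("%s:%d: rejecting record with start >= end", path, lineno)
                n_bad += 1
                continue
            name = fields[3] if len(fields) > 3 else f"{kind[:-1]}_{lineno}"
            if kind == "sites":
                out.append(SignalSite(chrom, start, end, mark=name, site_id=name))
            else:
                strand = fields[5] if len(fields) > 5 else "+"
                if strand == "+":
                    tss, tes = start, end
                else:
                    tss, tes = end, start
                out.append(GeneModel(name, chrom, strand, tss, tes))
    if not out:
        logger.warning("%s: no usable records", path)
    logger.info("read_intervals(%s, %s): %d kept, %d rejected", path, kind, len(out), n_bad)
    return out


def _read_gtf_genes(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            gene_id = None
            for attr in fields[8].split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start0 = start - 1  # GTF is 1-based inclusive
            if start0 >= end:
                logger.warning("%s:%d: rejecting empty gene interval", path, lineno)
                continue
            if strand == "+":
                tss, tes = start0, end
            else:
                tss, tes = end, start0
            genes.append(GeneModel(gene_id, chrom, strand, tss, tes))
    if not genes:
        logger.warning("%s: no gene records", path)
    return genes


def write_genes_bed(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (score column fixed at 0)."""
    with open(path, "w") as handle:
        for g in genes:
            start, end = g.span
            handle.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_sites_bed(sites: list[SignalSite], path: str | Path) -> None:
    with open(path, "w") as handle:
        for s in sites:
            handle.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.mark}\n")


# ---------------------------------------------------------------------------
# labelled region tables (promoters, gene bodies, ...)
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["chrom", "start", "end", "owner", "label"]


def write_regions(regions: pd.DataFrame | list[Region], path: str | Path) -> None:
    df = regions_to_frame(regions)
    df.to_csv(path, sep="\t", header=False, index=False, columns=REGION_COLUMNS)


def read_regions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=REGION_COLUMNS)
    bad = df["start"] >= df["end"]
    if bad.any():
        logger.warning("%s: rejecting %d regions with start >= end", path, int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    return df


def regions_to_frame(regions: pd.DataFrame | list[Region]) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.owner, r.label) for r in regions],
        columns=REGION_COLUMNS,
    )


# ---------------------------------------------------------------------------
# expression, layout, config
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x condition FPKM matrix (TSV with header, gene_id column)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: expected a 'gene_id' column")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    df = df.set_index("gene_id")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative FPKM values")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_layout(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            handle.write(f"{name}\t{length}\n")


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def cpg_positions_from_fasta(path: str | Path) -> dict[str, np.ndarray]:
    """Scan a FASTA for plus-strand CpG dinucleotides (position of the C)."""
    from pyfaidx import Fasta

    positions: dict[str, np.ndarray] = {}
    with Fasta(str(path)) as fasta:
        for name in fasta.keys():
            seq = str(fasta[name][:]).upper()
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
            positions[name] = hits.astype(np.int64)
    return positions
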