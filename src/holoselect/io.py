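"""Readers and writers for the pipeline's plain-text formats.

* Beagle genotype-likelihood text: marker, allele1, allele2, then three
  columns per sample (one likelihood per genotype), max-rescaled.
* sync-style pool TSV: chrom, pos, ref, alt, then one "ref:alt:depth"
  column per pool; pool roles and haploid sizes ride in ## header lines so
  a single file round-trips.
* gene table: BED-like TSV (chrom, start, end, gene_id; 0-based half-open).
* gene -> GO: gene_id TAB semicolon-joined GO ids.
* qPCR / metabolite / survivorship CSVs are plain pandas tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genolik import GenotypeLikelihoods
from .poolsel import PoolCounts

__all__ = [
    "write_beagle", "read_beagle",
    "write_sync", "read_sync",
    "write_gene_table", "read_gene_table",
    "write_gene_go", "read_gene_go",
]

_ALLELE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_ALLELE = {v: k for k, v in _ALLELE_CODE.items()}


def write_beagle(glt: GenotypeLikelihoods, path) -> None:
    """Write Beagle-GL text (marker, allele1, allele2, 3 cols/sample)."""
    path = Path(path)
    cols = ["marker", "allele1", "allele2"]
    for s in glt.samples:
        cols += [s] * 3
    markers = glt.site_labels()
    a1 = [_ALLELE_CODE.get(str(a).upper(), 0) for a in glt.sites["ref"]]
    a2 = [_ALLELE_CODE.get(str(a).upper(), 1) for a in glt.sites["alt"]]
    flat = glt.gl.reshape(glt.n_sites, -1)
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, marker in enumerate(markers):
            vals = "\t".join(f"{v:.6g}" for v in flat[i])
            fh.write(f"{marker}\t{a1[i]}\t{a2[i]}\t{vals}\n")


def read_beagle(path) -> GenotypeLikelihoods:
    """Read Beagle-GL text written by write_beagle (or ANGSD-style)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[3::3]
    raw = pd.read_csv(path, sep="\t", skiprows=1, header=None)
    markers = raw.iloc[:, 0].astype(str)
    chrom = markers.str.rsplit("_", n=1).str[0]
    pos = markers.str.rsplit("_", n=1).str[1].astype(int)
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "ref": [_CODE_ALLELE.get(int(c), "N") for c in raw.iloc[:, 1]],
        "alt": [_CODE_ALLELE.get(int(c), "N") for c in raw.iloc[:, 2]],
    })
    gl = raw.iloc[:, 3:].to_numpy(dtype=float).reshape(len(raw), len(samples), 3)
    return GenotypeLikelihoods(sites=sites, samples=samples, gl=gl)


def write_sync(pools: dict[tuple[str, str] | str, PoolCounts], path) -> None:
    """Write pooled counts as a self-describing sync-style TSV."""
    path = Path(path)
    items = list(pools.items())
    first = items[0][1]
    with path.open("w") as fh:
        for _, pc in items:
            fh.write(f"##pool\t{pc.name}\trole={pc.role}\tsize={pc.size}\n")
        names = "\t".join(pc.name for _, pc in items)
        fh.write(f"chrom\tpos\tref\talt\t{names}\n")
        sites = first.sites
        for i in range(len(first.ref)):
            cells = "\t".join(
                f"{pc.ref[i]}:{pc.alt[i]}:{pc.ref[i] + pc.alt[i]}" for _, pc in items
            )
            fh.write(
                f"{sites['chrom'].iloc[i]}\t{sites['pos'].iloc[i]}\t"
                f"{sites['ref'].iloc[i]}\t{sites['alt'].iloc[i]}\t{cells}\n"
            )


def read_sync(path) -> dict[str, PoolCounts]:
    """Read a sync-style TSV back into PoolCounts keyed by pool name."""
    path = Path(path)
    meta: dict[str, dict] = {}
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("##pool"):
                _, name, role_kv, size_kv = line.rstrip("\n").split("\t")
                meta[name] = {
                    "role": role_kv.split("=", 1)[1],
                    "size": int(size_kv.split("=", 1)[1]),
                }
                header_rows += 1
            else:
                break
    table = pd.read_csv(path, sep="\t", skiprows=header_rows)
    sites = table[["chrom", "pos", "ref", "alt"]].copy()
    out: dict[str, PoolCounts] = {}
    for name in table.columns[4:]:
        parts = table[name].str.split(":", expand=True).astype(int)
        info = meta.get(name, {"role": name, "size": 2})
        out[name] = PoolCounts(
            name=name, role=info["role"], size=info["size"], sites=sites,
            ref=parts[0].to_numpy(), alt=parts[1].to_numpy(),
        )
    return out


def write_gene_table(gene_table: pd.DataFrame, path) -> None:
    gene_table[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False
    )


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_go(gene_go: pd.DataFrame, path) -> None:
    """gene_id TAB semicolon-joined GO ids (one line per gene)."""
    grouped = gene_go.groupby("gene_id")["go_id"].apply(lambda s: ";".join(sorted(s)))
    with Path(path).open("w") as fh:
        for gene, gos in grouped.items():
            fh.write(f"{gene}\t{gos}\n")


def read_gene_go(path) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            gene, gos = line.rstrip("\n").split("\t")
            rows.extend({"gene_id": gene, "go_id": go} for go in gos.split(";") if go)
    return pd.DataFrame(rows)
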