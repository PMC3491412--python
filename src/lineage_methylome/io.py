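"""Readers and writers for the plain-text interchange formats.

TSV/CSV matrices go through pandas; BED and bedGraph are written 0-based
half-open; GMT is the usual tab-separated term / description / genes layout.
Float formatting is fixed so that identical in-memory objects serialize to
identical bytes (the pipeline's determinism contract).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"


def write_matrix(df: pd.DataFrame, path: Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_bed(df: pd.DataFrame, path: Path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False, float_format=FLOAT_FMT)


def read_bed(path: Path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_gmt(terms: dict[str, list[str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(terms):
            fh.write("\t".join([name, "synthetic"] + list(terms[name])) + "\n")


def read_gmt(path: Path) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                terms[parts[0]] = parts[2:]
    return terms


def write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_bundle(bundle, outdir: Path) -> None:
    """Serialize a synthetic bundle to its on-disk layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.beta, outdir / "beta.tsv", index_label="probe")
    write_matrix(bundle.detection_p, outdir / "detection.tsv", index_label="probe")
    bundle.samples.to_csv(outdir / "samples.csv")
    bundle.tss.to_csv(outdir / "tss.tsv", sep="\t", index_label="gene")
    probes = bundle.probes.copy()
    probes["start"] = probes["pos"]
    probes["end"] = probes["pos"] + 1
    probes["name"] = probes.index
    write_bed(probes, outdir / "probes.bed", extra_cols=["name"])
    write_bed(bundle.cgi, outdir / "cgi.bed", extra_cols=["name"])
    write_bed(bundle.repeats, outdir / "repeats.bed", extra_cols=["class"])
    write_bed(bundle.indel_purified, outdir / "indel_purified.bed")
    write_bed(bundle.conservation, outdir / "conservation.bedgraph", extra_cols=["score"])
    write_bed(bundle.lincrna, outdir / "lincrna.bed", extra_cols=["name"])
    write_matrix(bundle.expression, outdir / "expression.tsv", index_label="gene")
    write_matrix(bundle.expression_reps, outdir / "expression_reps.tsv", index_label="gene")
    write_matrix(bundle.presence, outdir / "presence.tsv", index_label="gene")
    write_gmt(bundle.terms, outdir / "terms.gmt")
    write_matrix(bundle.cgi_counts, outdir / "cgi_counts.tsv", index_label="cgi")
    bundle.seq_samples.to_csv(outdir / "pairing.csv")
    (outdir / "truth.json").write_text(bundle.truth.to_json() + "\n")
    (outdir / "config.json").write_text(bundle.config.to_json() + "\n")
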