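"""Readers and writers for every on-disk artifact.

Formats: expression matrix and sample attributes as TSV, probe-level chips
as long-form TSV (row, col, probeset_id, intensity; raw scale on disk,
log2 with floor 1.0 in memory), gene sets as GMT, promoters as FASTA
(via Biopython), motifs as JASPAR PFM text (via Bio.motifs), decompositions
as TSV triples with metadata header lines, ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .eigen import EigenDecomposition
from .enrichment import GeneSetCollection
from .motif import PWM
from .preprocess import ProbeChip
from .profiles import ExpressionProfile
from .simulate import GroundTruth

FLOAT_FMT = "%.10g"


# ----------------------------------------------------------------------
# expression profiles
# ----------------------------------------------------------------------

def write_expression_tsv(profile: ExpressionProfile, path) -> None:
    profile.values.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def write_attributes_tsv(profile: ExpressionProfile, path) -> None:
    if profile.attributes is None:
        raise ValueError("profile has no attribute table to write")
    profile.attributes.to_csv(path, sep="\t", index_label="sample_id",
                              float_format=FLOAT_FMT)


def read_expression_tsv(path, attributes_path=None) -> ExpressionProfile:
    """Load a gene x sample TSV (header = sample ids) and optional attributes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicated gene id in {path}: {dup[0]!r}")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        raise ValueError(f"non-numeric expression cells in columns: {list(bad[:5])}")
    attrs = read_attributes_tsv(attributes_path) if attributes_path else None
    return ExpressionProfile(df, attrs)


def read_attributes_tsv(path) -> pd.DataFrame:
    attrs = pd.read_csv(path, sep="\t", index_col=0)
    if attrs.index.has_duplicates:
        dup = attrs.index[attrs.index.duplicated()].unique()
        raise ValueError(f"duplicated sample id in {path}: {dup[0]!r}")
    return attrs


# ----------------------------------------------------------------------
# probe chips (long-form TSV)
# ----------------------------------------------------------------------

def write_chip_tsv(chip: ProbeChip, path) -> None:
    """Serialize a chip as (row, col, probeset_id, intensity); raw intensity scale."""
    rows, cols = chip.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    df = pd.DataFrame(
        {
            "row": rr.ravel(),
            "col": cc.ravel(),
            "probeset_id": chip.probeset_map.ravel(),
            "intensity": np.exp2(chip.values.ravel()),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_chip_tsv(path) -> ProbeChip:
    """Load a long-form chip TSV; intensities are floored at 1.0 and log2-taken."""
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str}, keep_default_na=False)
    required = {"row", "col", "probeset_id", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"chip TSV must have columns {sorted(required)}")
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    values = np.full((rows, cols), np.nan)
    pmap = np.full((rows, cols), "", dtype="U32")
    values[df["row"], df["col"]] = np.log2(np.maximum(df["intensity"].to_numpy(), 1.0))
    pmap[df["row"], df["col"]] = df["probeset_id"].to_numpy()
    if np.isnan(values).any():
        raise ValueError("chip TSV does not cover the full grid")
    return ProbeChip(values, pmap)


# ----------------------------------------------------------------------
# gene sets (GMT)
# ----------------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_gmt(path, universe) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return GeneSetCollection(sets=sets, universe=list(universe))


# ----------------------------------------------------------------------
# promoters (FASTA) and motifs (JASPAR PFM)
# ----------------------------------------------------------------------

def write_promoters_fasta(promoters: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()]
    SeqIO.write(records, path, "fasta")


def read_promoters_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_jaspar_pfm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} {pwm.name}\n")
        for base, row in zip("ACGT", pwm.counts):
            fh.write(f"{base} [ " + " ".join(FLOAT_FMT % v for v in row) + " ]\n")


def read_jaspar_pfm(path, pseudocount: float = 0.01,
                    background=None) -> list[PWM]:
    """Read one or more JASPAR-format PFMs (4-row count matrices)."""
    kwargs = {}
    if background is not None:
        kwargs["background"] = np.asarray(background, dtype=float)
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            name = m.name or m.matrix_id or Path(path).stem
            out.append(PWM(name=str(name), counts=counts, pseudocount=pseudocount, **kwargs))
    if not out:
        raise ValueError(f"no motif found in {path}")
    return out


# ----------------------------------------------------------------------
# decompositions
# ----------------------------------------------------------------------

def write_decomposition(dec: EigenDecomposition, prefix) -> None:
    """Three TSVs: singular values (+cumulative %), gene loadings, sample loadings."""
    from .eigen import contribution_percentages

    prefix = Path(prefix)
    header = f"# centering: {dec.centering}\n# anchors: {json.dumps(dec.anchors, sort_keys=True)}\n"
    cum = contribution_percentages(dec.rho) if dec.rho.sum() > 0 else np.zeros_like(dec.rho)
    values = pd.DataFrame(
        {"component": np.arange(1, dec.n_components + 1), "rho": dec.rho,
         "cumulative_pct": cum}
    )
    for suffix, frame, index_label in (
        ("values", values, None),
        ("gene_loadings",
         pd.DataFrame(dec.u, index=dec.genes,
                      columns=[f"u{k + 1}" for k in range(dec.n_components)]),
         "gene_id"),
        ("sample_loadings",
         pd.DataFrame(dec.v, index=dec.samples,
                      columns=[f"v{k + 1}" for k in range(dec.n_components)]),
         "sample_id"),
    ):
        path = prefix.parent / f"{prefix.name}.{suffix}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", float_format=FLOAT_FMT,
                         index=index_label is not None, index_label=index_label)


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "rho_endo": truth.rho_endo,
        "rho_exo": truth.rho_exo,
        "genes": truth.genes,
        "samples": truth.samples,
        "endo_u": truth.endo_u.tolist(),
        "endo_v": truth.endo_v.tolist(),
        "exo_u": truth.exo_u.tolist(),
        "exo_v": truth.exo_v.tolist(),
        "planted_sets": truth.planted_sets,
        "planted_motif_genes": truth.planted_motif_genes,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        endo_u=np.asarray(payload["endo_u"]),
        endo_v=np.asarray(payload["endo_v"]),
        exo_u=np.asarray(payload["exo_u"]),
        exo_v=np.asarray(payload["exo_v"]),
        rho_endo=payload["rho_endo"],
        rho_exo=payload["rho_exo"],
        genes=payload["genes"],
        samples=payload["samples"],
        planted_sets=payload["planted_sets"],
        planted_motif_genes=payload["planted_motif_genes"],
    )
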