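"""Per-cluster gene lists and mean brain association patterns.

Each SNP cluster is mapped to the set of closest genes (from a user-supplied
SNP-to-gene table) for external pathway-enrichment upload, and to the mean
of its members' normalized association rows — the average effect of the SNP
group on every ROI — for external brain-map annotation.  No web services are
called; exports are plain text.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .association import AssociationMap

__all__ = ["ClusterAnnotation", "mean_brain_pattern", "cluster_gene_list", "export_annotation", "annotate_clusters"]


@dataclass
class ClusterAnnotation:
    cluster_index: int
    snp_ids: list[str]
    gene_symbols: list[str]  # deduplicated, sorted
    unmapped_snps: list[str]
    mean_pattern: np.ndarray  # ROI-indexed means of normalized rows
    roi_ids: list[str]


def mean_brain_pattern(assoc: AssociationMap, assignment: dict[str, int], cluster_index: int) -> np.ndarray:
    """Arithmetic mean over the cluster members' normalized map rows."""
    if not assoc.normalized:
        raise ValueError("mean_brain_pattern expects a row-normalized map")
    members = [i for i, s in enumerate(assoc.snp_ids) if assignment.get(s) == cluster_index]
    if not members:
        raise ValueError(f"cluster {cluster_index} is empty")
    return assoc.values[members].mean(axis=0)


def cluster_gene_list(
    assignment: dict[str, int], snp_gene_map: dict[str, str]
) -> dict[int, tuple[list[str], list[str]]]:
    """Per-cluster (sorted unique gene symbols, unmapped SNP ids)."""
    out: dict[int, tuple[list[str], list[str]]] = {}
    for k in sorted(set(assignment.values())):
        snps = sorted(s for s, c in assignment.items() if c == k)
        genes = sorted({snp_gene_map[s] for s in snps if s in snp_gene_map})
        unmapped = [s for s in snps if s not in snp_gene_map]
        out[k] = (genes, unmapped)
    return out


def annotate_clusters(
    assoc: AssociationMap,
    assignment: dict[str, int],
    snp_gene_map: dict[str, str] | None = None,
) -> list[ClusterAnnotation]:
    snp_gene_map = snp_gene_map or {}
    genes = cluster_gene_list(assignment, snp_gene_map)
    annotations = []
    for k in sorted(set(assignment.values())):
        gene_list, unmapped = genes[k]
        annotations.append(
            ClusterAnnotation(
                cluster_index=k,
                snp_ids=sorted(s for s, c in assignment.items() if c == k),
                gene_symbols=gene_list,
                unmapped_snps=unmapped,
                mean_pattern=mean_brain_pattern(assoc, assignment, k),
                roi_ids=list(assoc.roi_ids),
            )
        )
    return annotations


def export_annotation(annotations: list[ClusterAnnotation], out_dir: str | Path) -> list[Path]:
    """Write per-cluster gene lists (one symbol per line, paste-ready for
    enrichment tools), mean-pattern CSVs (roi_id, mean_value), and one
    unmapped-SNP report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    unmapped_all: list[tuple[int, str]] = []
    for ann in annotations:
        gene_path = out_dir / f"cluster{ann.cluster_index}_genes.txt"
        gene_path.write_text("".join(g + "\n" for g in ann.gene_symbols))
        written.append(gene_path)
        pattern_path = out_dir / f"cluster{ann.cluster_index}_mean_pattern.csv"
        with open(pattern_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["roi_id", "mean_value"])
            for roi, val in zip(ann.roi_ids, ann.mean_pattern):
                writer.writerow([roi, repr(float(val))])
        written.append(pattern_path)
        unmapped_all.extend((ann.cluster_index, s) for s in ann.unmapped_snps)
    report = out_dir / "unmapped_snps.tsv"
    report.write_text("".join(f"{k}\t{s}\n" for k, s in unmapped_all))
    written.append(report)
    return written


def read_mean_pattern(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Round-trip reader for the mean-pattern CSV."""
    rois, vals = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for roi, val in reader:
            rois.append(roi)
            vals.append(float(val))
    return rois, np.array(vals)
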