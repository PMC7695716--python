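"""Dataset export: triplet matrices, bedGraph tracks, BED/BEDPE truth, manifest."""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from . import contacts as ct
from .synthetic import CONDITIONS, SyntheticDataset
from .tracks import write_bedgraph

__all__ = ["write_dataset"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Write every simulated artefact as plain text plus a hash manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    files: list[Path] = []

    for res, by_cond in dataset.contacts.items():
        for cond, reps in by_cond.items():
            for r, mats in enumerate(reps):
                for chrom, mat in mats.items():
                    p = out / f"contacts_{cond}_rep{r}_{chrom}_{res}.txt"
                    ct.write_matrix(mat, p)
                    files.append(p)
        for chrom in cfg.chroms():
            p = out / f"bins_{chrom}_{res}.bed"
            ct.write_bin_table(ct.make_bin_table(chrom, cfg.chrom_length, res), p)
            files.append(p)

    for (cond, drb), tracks in dataset.coverage.items():
        tag = f"{cond}{'_drb' if drb else ''}"
        for name, obj in tracks.items():
            if name == "input":
                p = out / f"coverage_{tag}_input.bedgraph"
                write_bedgraph(obj, p)
                files.append(p)
            else:
                for r, track in enumerate(obj):
                    p = out / f"coverage_{tag}_{name}_rep{r}.bedgraph"
                    write_bedgraph(track, p)
                    files.append(p)

    t = dataset.truth
    tables = {
        "genes.tsv": t.genes,
        "enhancers.bed.tsv": t.enhancers,
        "promoters.bed.tsv": t.promoters,
        "expression.tsv": t.expression,
        "islands.bed.tsv": t.islands,
        "ctcf_sites.tsv": t.ctcf_sites,
        "diff_pairs.tsv": t.diff_pairs,
        "ep_changes.tsv": t.ep_changes,
    }
    for name, df in tables.items():
        p = out / f"truth_{name}"
        df.to_csv(p, sep="\t", index=False)
        files.append(p)
    p = out / "truth_loops.bedpe"
    with open(p, "w") as fh:
        for r in t.loops.itertuples():
            fh.write(f"{r.chrom}\t{r.anchor1 - 10_000}\t{r.anchor1 + 10_000}\t"
                     f"{r.chrom}\t{r.anchor2 - 10_000}\t{r.anchor2 + 10_000}\n")
    files.append(p)

    manifest = {
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "conditions": list(CONDITIONS),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out / "manifest.yaml"
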