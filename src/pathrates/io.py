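"""Readers and writers for the plain-text formats of the pipeline.

Expression matrices are tab-separated text with a gene-id first column
and a header row of species names; gene sets are GMT (term, description,
genes...) or two-column term<TAB>gene files, auto-detected; results go
out as CSV with the standard pathway-table schema.  All floats are
written with 9 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import DataError
from .tree import CalibratedTree, YEAST_NEWICK, parse_newick, yeast_fixture_tree

logger = logging.getLogger("pathrates")

FLOAT_FORMAT = "%.9g"

#: the five fixed columns of the pathway results table
RESULT_COLUMNS = {
    "term": "GO term",
    "n_genes": "N",
    "best_model": "Model",
    "best_waic": "wAIC",
    "parameter": "Constraint or shift parameter",
}


def read_tree(path: str | Path) -> CalibratedTree:
    """Parse a Newick file into a validated calibrated tree."""
    return parse_newick(Path(path).read_text())


def read_expression(
    path: str | Path,
    *,
    log2_transform: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Read a genes x species expression TSV.

    Empty cells become missing values.  With ``log2_transform``, values
    are mapped through log2(x + pseudocount) — for raw (already
    normalized) counts; otherwise values are taken as log expression.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise DataError(f"cannot parse expression file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene id(s): {dups}")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise DataError(f"non-numeric value in column {col!r}: {exc}") from exc
    if log2_transform:
        out = np.log2(out + pseudocount)
    return out


def validate_species(expr: pd.DataFrame, tree: CalibratedTree) -> None:
    """Require every expression column to name a tree tip."""
    missing = [c for c in expr.columns if c not in tree.tip_names]
    if missing:
        raise DataError(f"expression species not on the tree: {missing}")


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix as TSV at full precision."""
    expr.to_csv(path, sep="\t", float_format="%.17g")


def read_genesets(path: str | Path) -> dict[str, list[str]]:
    """Read a gene-set file, auto-detecting the dialect.

    GMT lines carry term, description, then genes; two-column lines carry
    term<TAB>gene.  Mixing dialects is an error; duplicate genes within a
    term are dropped with a warning.
    """
    lines = Path(path).read_text().splitlines()
    records = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2 or any(not f.strip() for f in fields[:2]):
            raise DataError(f"unparseable gene-set line {lineno}: {raw!r}")
        records.append((lineno, fields))
    if not records:
        raise DataError(f"gene-set file {path} is empty")
    widths = {len(f) > 2 for _, f in records}
    if len(widths) > 1:
        raise DataError("mixed GMT / two-column dialects in one gene-set file")
    is_gmt = widths.pop()
    out: dict[str, list[str]] = {}
    for lineno, fields in records:
        term = fields[0].strip()
        genes = [g.strip() for g in (fields[2:] if is_gmt else fields[1:2]) if g.strip()]
        bucket = out.setdefault(term, [])
        for g in genes:
            if g in bucket:
                logger.warning(
                    "read_genesets: duplicate gene %r in term %s (line %d)",
                    g, term, lineno,
                )
            else:
                bucket.append(g)
    return out


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a pathway scan table as CSV.

    The header carries the five standard columns (GO term, N, Model,
    wAIC, Constraint or shift parameter) followed by one weight column
    per candidate model; floats use 9 significant digits; row order is
    preserved.
    """
    out = table.rename(columns=RESULT_COLUMNS)
    ordered = [c for c in RESULT_COLUMNS.values() if c in out.columns]
    ordered += [c for c in out.columns if c not in ordered]
    out = out[ordered]
    if out.empty:
        logger.warning("write_results: empty results table")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_fit_table(fits, weights, path: str | Path) -> None:
    """Write one pathway's per-model fit summary as CSV."""
    rows = []
    for fit, w in zip(fits, weights):
        row = {
            "model": fit.spec.name,
            "k": fit.k,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "waic": float(w),
            "converged": fit.converged,
            "n_genes": fit.n_genes_used,
        }
        row.update({p: v for p, v in fit.params.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ----------------------------------------------------------------------
def generate_fixtures(outdir: str | Path, seed: int) -> dict[str, Path]:
    """Write a self-contained demo data set: the packaged four-taxon
    tree, a 100-gene expression TSV simulated under a S. paradoxus-like
    tip shift (alpha = 3, beta = 2, r = 5), and a toy three-term gene-set
    file.  Byte-identical across calls with the same seed."""
    from .simulate import SimulationConfig, replicate_rng, simulate_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = yeast_fixture_tree()
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(YEAST_NEWICK + "\n")

    cfg = SimulationConfig(
        family="BM", alpha=3.0, beta=2.0,
        shift_tips=("par",), shift_r=5.0, n_genes=100, seed=seed,
    )
    sim = simulate_dataset(cfg, tree, replicate_rng(seed, 0))
    expr_path = outdir / "expression.tsv"
    write_expression(sim.expression, expr_path)

    genes = list(sim.expression.index)
    sets_path = outdir / "genesets.gmt"
    lines = [
        "PW:0001\tdemo pathway 1\t" + "\t".join(genes[:40]),
        "PW:0002\tdemo pathway 2\t" + "\t".join(genes[40:80]),
        "PW:0003\tdemo pathway 3\t" + "\t".join(genes[80:]),
    ]
    sets_path.write_text("\n".join(lines) + "\n")
    return {"tree": tree_path, "expression": expr_path, "genesets": sets_path}
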