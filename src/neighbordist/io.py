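"""Reading and writing the package's on-disk formats.

TSV is the canonical dialect (tab-separated, '.' decimal, UTF-8); comma-
separated files are accepted on read.  Formats:

* continuous matrices — instances as rows, a header row of attribute names;
* genotype matrices — integer TSV in {0,1,2}, plus a locus-annotation TSV
  with columns ``locus_id``, ``maf``, ``encoding``;
* correlation stacks — p(p-1) x m TSV plus a JSON sidecar (``<path>.meta.json``)
  declaring p and m;
* distance matrices — square TSV with instance IDs as header and index.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._types import (
    ContinuousMatrix,
    CorrelationStack,
    DistanceMatrix,
    GenotypeData,
    MetricSpec,
)

__all__ = [
    "read_matrix",
    "read_continuous",
    "write_continuous",
    "read_genotypes",
    "write_genotypes",
    "read_stack",
    "write_stack",
    "read_distance",
    "write_distance",
]


def _read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", **kw)


def read_continuous(path) -> ContinuousMatrix:
    df = _read_table(path)
    values = df.to_numpy(dtype=float)
    return ContinuousMatrix(values, attribute_names=list(df.columns))


def write_continuous(X: ContinuousMatrix, path) -> None:
    names = X.attribute_names or [f"attr{i+1}" for i in range(X.p)]
    pd.DataFrame(X.values, columns=names).to_csv(path, sep="\t", index=False)


def read_genotypes(path, annotation_path: Optional[str] = None) -> GenotypeData:
    """Read a genotype TSV and (optionally) its locus-annotation table.

    Non-{0,1,2} entries are rejected with the offending loci named.
    """
    df = _read_table(path)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1, 2))
    if bad.any():
        rows, cols = np.nonzero(bad)
        detail = ", ".join(
            f"(row {r + 1}, locus {df.columns[c]})" for r, c in zip(rows[:5], cols[:5])
        )
        raise ValueError(f"genotype entries outside {{0,1,2}} at {detail}")
    maf = encoding = None
    if annotation_path is not None:
        ann = _read_table(annotation_path)
        required = {"locus_id", "maf", "encoding"}
        if not required <= set(ann.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        ann = ann.set_index("locus_id").loc[list(df.columns)]
        maf = ann["maf"].to_numpy(dtype=float)
        encoding = ann["encoding"].to_numpy(dtype=object)
    return GenotypeData(
        genotypes=values.astype(np.int8), maf=maf, encoding=encoding,
        maf_source="supplied" if maf is not None else "unknown",
    )


def write_genotypes(G: GenotypeData, path, annotation_path: Optional[str] = None) -> None:
    names = [f"locus{i+1}" for i in range(G.p)]
    pd.DataFrame(G.genotypes, columns=names).to_csv(path, sep="\t", index=False)
    if annotation_path is not None:
        if G.maf is None or G.encoding is None:
            raise ValueError("annotation output requires maf and encoding")
        pd.DataFrame(
            {"locus_id": names, "maf": G.maf, "encoding": G.encoding}
        ).to_csv(annotation_path, sep="\t", index=False)


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def read_stack(path) -> CorrelationStack:
    """Read a correlation stack TSV; its sidecar declares p and m."""
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing stack sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    p, m = int(meta["p"]), int(meta["m"])
    if values.shape != (p * (p - 1), m):
        raise ValueError(
            f"stack shape {values.shape} does not match sidecar "
            f"(expected {p * (p - 1)} rows x {m} columns for p={p})"
        )
    return CorrelationStack(values, p=p, standardized=bool(meta.get("standardized", True)))


def write_stack(S: CorrelationStack, path) -> None:
    pd.DataFrame(S.values).to_csv(path, sep="\t", index=False, header=False)
    _sidecar_path(path).write_text(
        json.dumps({"p": S.p, "m": S.m, "standardized": S.standardized})
    )


def read_distance(path, metric: Optional[MetricSpec] = None) -> DistanceMatrix:
    df = _read_table(path, index_col=0)
    return DistanceMatrix(
        df.to_numpy(dtype=float),
        metric=metric or MetricSpec("lq", q=1),
        ids=list(df.columns),
    )


def write_distance(D: DistanceMatrix, path) -> None:
    ids = D.ids or [f"inst{i+1}" for i in range(D.m)]
    pd.DataFrame(D.values, index=ids, columns=ids).to_csv(path, sep="\t")


_READERS = {
    "continuous": read_continuous,
    "genotype": read_genotypes,
    "stack": read_stack,
    "distance": read_distance,
}


def read_matrix(path, kind: str):
    """Dispatch to the typed reader for ``kind``."""
    try:
        reader = _READERS[kind]
    except KeyError:
        raise ValueError(f"unknown matrix kind {kind!r}; choose from {sorted(_READERS)}")
    return reader(path)
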