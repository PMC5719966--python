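"""End-to-end construction: Phase 1 per string, then the Phase-2 merge."""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import List, Optional, Tuple, Union

from .collection_io import (
    Collection,
    CollectionStore,
    GESARecord,
    IOStats,
    gesa_read,
)
from .merge import MergeConfig, MergeResult, merge
from .phase1 import build_esa

__all__ = ["build_collection_esas", "build_gesa", "gesa_records"]


def build_collection_esas(
    collection: Collection,
    p: int,
    outdir: Union[str, Path],
    *,
    induction_aware: bool = True,
    width: int = 4,
    stats: Optional[IOStats] = None,
    prefix: str = "string",
) -> List[Path]:
    """Run Phase 1 for every string; returns the .esa paths in rank order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in collection.strings:
        path = outdir / f"{prefix}.{rec.id}.esa"
        build_esa(
            rec, p, induction_aware=induction_aware, path=path,
            width=width, stats=stats,
        )
        paths.append(path)
    return paths


def build_gesa(
    collection: Collection,
    config: MergeConfig,
    workdir: Optional[Union[str, Path]] = None,
    *,
    out_name: str = "collection.gesa",
    width: int = 4,
) -> Tuple[MergeResult, List[GESARecord]]:
    """Build the generalized enhanced suffix array of a collection.

    Phase-1 files are written under ``workdir`` (a temporary directory by
    default, deleted afterwards) with induction-aware zeroing matching
    ``config.use_induction``; the merged output is read back and returned
    together with the :class:`MergeResult`.
    """
    if workdir is None:
        with tempfile.TemporaryDirectory(prefix="gesa_work_") as tmp:
            return _run(collection, config, Path(tmp), out_name, width)
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    return _run(collection, config, wd, out_name, width)


def _run(collection, config, wd, out_name, width):
    stats = IOStats()
    store = CollectionStore(collection, stats=stats)
    esa_paths = build_collection_esas(
        collection, config.p, wd / "esa",
        induction_aware=config.use_induction, width=width, stats=stats,
    )
    out = wd / out_name
    result = merge(
        esa_paths, store, config, out, width=width, spill_dir=wd / "spill"
    )
    records = list(gesa_read(out))
    return result, records


def gesa_records(path: Union[str, Path]) -> List[GESARecord]:
    """Convenience: load a full .gesa file into memory."""
    return list(gesa_read(path))
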