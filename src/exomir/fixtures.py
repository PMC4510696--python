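"""Packaged fixture tables: published miRNA enrichment category lists and
absolute miR-100 copy numbers, shipped as TSV and re-emitted on demand."""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

FIXTURE_FILES = (
    "table1_cells_enriched.tsv",
    "table2_exosome_enriched.tsv",
    "mir100_absolute_copies.tsv",
)


def fixture_text(name: str) -> str:
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_FILES}")
    return resources.files("exomir.data").joinpath(name).read_text()


def write_fixture_tables(outdir: str | Path) -> dict[str, Path]:
    """Emit the packaged category lists and copy-number table into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in FIXTURE_FILES:
        p = outdir / name
        p.write_text(fixture_text(name))
        paths[name] = p
    return paths


def load_copy_numbers() -> pd.DataFrame:
    """Absolute miR-100 copies per input RNA (mean, SEM) for the three
    co-culture conditions: no donor, AI-CTL donor, AI-100 donor."""
    import io

    return pd.read_csv(io.StringIO(fixture_text("mir100_absolute_copies.tsv")), sep="\t")
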