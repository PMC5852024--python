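"""Packaged reference partition: the published 2013 disease module table.

A transcription of the nine-module 2013 partition (module colour, analysis
code, disease name) reported for a national claims cohort, shipped as CSV
with an integrity checksum.  It provides label-only module sets usable for
size reports and Jaccard comparisons against partitions computed here.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from comorbnet.topology import ModulePartition

FIXTURE_NAME = "modules_2013.csv"
FIXTURE_SHA256 = "922f98031df32a7733b17fe6f7ae05f64adff86c91ab4975ad75620960f1fd50"

#: Published per-colour module sizes for 2013.
PUBLISHED_SIZES = {
    "turquoise": 39,
    "blue": 32,
    "brown": 27,
    "yellow": 25,
    "green": 25,
    "red": 24,
    "black": 24,
    "pink": 22,
    "magenta": 21,
}


def fixture_path() -> Path:
    return Path(str(resources.files("comorbnet").joinpath("data", FIXTURE_NAME)))


def load_fixture_table(path: str | Path | None = None, *, verify: bool = True) -> pd.DataFrame:
    """Load the (module, code, disease) table; checksum-verified by default.

    Pass an explicit ``path`` to substitute a corrected transcription (the
    override skips the checksum).
    """
    override = path is not None
    path = Path(path) if override else fixture_path()
    data = path.read_bytes()
    if verify and not override:
        digest = hashlib.sha256(data).hexdigest()
        if digest != FIXTURE_SHA256:
            raise RuntimeError(
                f"fixture {path} integrity check failed: sha256 {digest} != {FIXTURE_SHA256}"
            )
    df = pd.read_csv(path, dtype={"code": str})
    missing = {"module", "code", "disease"} - set(df.columns)
    if missing:
        raise ValueError(f"fixture lacks column(s) {sorted(missing)}")
    if df["code"].duplicated().any():
        raise ValueError("fixture codes are not unique")
    return df


def load_fixture_partition(path: str | Path | None = None) -> ModulePartition:
    """The published 2013 partition as a labels-only :class:`ModulePartition`."""
    df = load_fixture_table(path)
    labels = pd.Series(df["module"].to_numpy(), index=df["code"].to_numpy(), name="module")
    return ModulePartition(labels=labels)
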