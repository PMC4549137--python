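"""Region atlases for ROI-parcellated brain data.

The package ships the 116-region Automated Anatomical Labeling (AAL)
parcellation label list: 45 bilateral cortical regions, 9 bilateral
cerebellar regions and 8 midline vermis regions (90 + 18 + 8 = 116).
An atlas fixes the region ordering used by every matrix and edge index
in the pipeline.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

REGION_CLASSES = ("cortical", "cerebellar", "vermis")
HEMISPHERES = ("left", "right", "midline")


@dataclass(frozen=True)
class Region:
    index: int  # 1-based atlas index
    name: str
    region_class: str
    hemisphere: str


class RegionAtlas:
    """Ordered, named brain parcellation.

    Region names must be unique and indices contiguous from 1 to R.
    """

    def __init__(self, regions: Sequence[Region]):
        regions = tuple(regions)
        if not regions:
            raise ValueError("atlas has no regions")
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")
        if [r.index for r in regions] != list(range(1, len(regions) + 1)):
            raise ValueError("region indices must be contiguous from 1")
        for r in regions:
            if r.region_class not in REGION_CLASSES:
                raise ValueError(f"unknown region class {r.region_class!r}")
            if r.hemisphere not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {r.hemisphere!r}")
        self.regions = regions
        self._by_name = {r.name: r for r in regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Region:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"region {name!r} not in atlas") from None

    def position(self, name: str) -> int:
        """0-based position of a region in matrix/vector order."""
        return self[name].index - 1

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in REGION_CLASSES}
        for r in self.regions:
            counts[r.region_class] += 1
        return counts

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        required = {"index", "name", "class", "hemisphere"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table missing columns {sorted(missing)}")
        return cls(
            Region(int(row["index"]), str(row["name"]), str(row["class"]),
                   str(row["hemisphere"]))
            for _, row in df.iterrows()
        )

    @classmethod
    def from_tsv(cls, path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.regions],
                "name": [r.name for r in self.regions],
                "class": [r.region_class for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_aal116() -> RegionAtlas:
    """The packaged AAL 116-region label list."""
    ref = importlib.resources.files("scaconn.data") / "aal116.tsv"
    with importlib.resources.as_file(ref) as path:
        atlas = RegionAtlas.from_tsv(path)
    assert len(atlas) == 116
    return atlas
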