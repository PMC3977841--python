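"""Subjects × regions copy-number status matrix, the hand-off to association."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VALID_STATUSES = {"loss", "unchanged", "gain", "missing"}


@dataclass
class RegionStatusMatrix:
    """Per-subject copy-number class per target region.

    ``statuses``: DataFrame indexed by subject id, one column per region,
    values in {loss, unchanged, gain, missing}. ``groups``: Series mapping
    subject id -> "case" | "control".
    """

    statuses: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.statuses.to_numpy().ravel()) - VALID_STATUSES
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}")
        self.groups = self.groups.reindex(self.statuses.index)
        if self.groups.isna().any():
            missing = self.statuses.index[self.groups.isna()][:3].tolist()
            raise ValueError(f"subjects without group label: {missing}")
        bad_groups = set(self.groups) - {"case", "control"}
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def regions(self) -> list[str]:
        return list(self.statuses.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.statuses.index)

    def subset(self, subjects) -> "RegionStatusMatrix":
        return RegionStatusMatrix(
            self.statuses.loc[subjects], self.groups.loc[subjects]
        )

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        out = self.statuses.copy()
        out.insert(0, "group", self.groups)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t", index_label="subject")

    @classmethod
    def from_tsv(cls, path) -> "RegionStatusMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="subject")
        groups = df.pop("group")
        return cls(df, groups)
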