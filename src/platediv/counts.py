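"""Count records for two-color doublet experiments.

A two-color experiment mixes red- and green-labeled platelets in semisolid
medium and tallies, over the surveyed microscopic fields, the total platelets
of each color and the doublets of each color combination.  Five integers
fully describe one experiment/condition and are the entire input to the
division-fraction estimator.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

CSV_COLUMNS = ["experiment", "condition", "n_red", "n_green", "d_rr", "d_gg", "d_rg"]

_COUNT_FIELDS = ("n_red", "n_green", "d_rr", "d_gg", "d_rg")


class InvalidCountsError(ValueError):
    """Raised when a count record violates the accounting identities."""


@dataclasses.dataclass(frozen=True)
class FieldCounts:
    """Aggregate counts of one two-color experiment.

    ``n_red``/``n_green`` are the *total* platelets of each color seen across
    all surveyed fields (singlets plus platelets bound in doublets), so the
    singlet counts are implied:  ``s_r = n_red - 2*d_rr - d_rg`` and
    ``s_g = n_green - 2*d_gg - d_rg``.
    """

    experiment_id: str
    condition: str
    n_red: int
    n_green: int
    d_rr: int
    d_gg: int
    d_rg: int

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                if not (hasattr(v, "is_integer") and float(v).is_integer()):
                    raise InvalidCountsError(
                        f"{self.experiment_id}: {name} must be an integer, got {v!r}"
                    )
                object.__setattr__(self, name, int(v))
                v = int(v)
            if v < 0:
                raise InvalidCountsError(
                    f"{self.experiment_id}: {name} must be >= 0, got {v}"
                )
        if self.singlets_red < 0 or self.singlets_green < 0:
            raise InvalidCountsError(
                f"{self.experiment_id}: totals too small for the doublet counts "
                f"(need n_red >= 2*d_rr + d_rg and n_green >= 2*d_gg + d_rg; "
                f"got n_red={self.n_red}, n_green={self.n_green}, "
                f"d_rr={self.d_rr}, d_gg={self.d_gg}, d_rg={self.d_rg})"
            )

    @property
    def singlets_red(self) -> int:
        return self.n_red - 2 * self.d_rr - self.d_rg

    @property
    def singlets_green(self) -> int:
        return self.n_green - 2 * self.d_gg - self.d_rg

    @property
    def total_doublets(self) -> int:
        return self.d_rr + self.d_gg + self.d_rg

    def swapped(self) -> "FieldCounts":
        """The same experiment with the color labels exchanged."""
        return FieldCounts(
            self.experiment_id,
            self.condition,
            n_red=self.n_green,
            n_green=self.n_red,
            d_rr=self.d_gg,
            d_gg=self.d_rr,
            d_rg=self.d_rg,
        )


def read_counts_csv(path: str | Path) -> list[FieldCounts]:
    """Read count records from a CSV with the canonical column schema."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidCountsError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                FieldCounts(
                    experiment_id=str(row["experiment"]),
                    condition=str(row["condition"]),
                    n_red=int(row["n_red"]),
                    n_green=int(row["n_green"]),
                    d_rr=int(row["d_rr"]),
                    d_gg=int(row["d_gg"]),
                    d_rg=int(row["d_rg"]),
                )
            )
        except InvalidCountsError as err:
            raise InvalidCountsError(f"{path}, row {i + 1}: {err}") from err
    return records


def write_counts_csv(records: Iterable[FieldCounts], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "experiment": r.experiment_id,
                "condition": r.condition,
                "n_red": r.n_red,
                "n_green": r.n_green,
                "d_rr": r.d_rr,
                "d_gg": r.d_gg,
                "d_rg": r.d_rg,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("platediv").joinpath("data", name)))


def load_semisolid_counts() -> list[FieldCounts]:
    """Packaged counts of the six semisolid-culture experiments (MCX1-MCX6),
    each observed before (initial) and after six hours of culture."""
    return read_counts_csv(_fixture_path("semisolid_counts.csv"))


def load_cytoskeletal_counts() -> list[FieldCounts]:
    """Packaged counts of the cytoskeletal-inhibitor experiments (taxol,
    nocodazole, cytochalasin D), mock- vs drug-treated."""
    return read_counts_csv(_fixture_path("cytoskeletal_counts.csv"))


def load_cfse_division_table() -> pd.DataFrame:
    """Packaged per-sort CFSE dye-dilution division percentages
    (columns: sort, timepoint, mfi, percent_divided)."""
    return pd.read_csv(_fixture_path("cfse_division_table.csv"))
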