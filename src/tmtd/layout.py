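"""Channel layouts for isobaric multiplex experiments.

A :class:`ChannelLayout` describes one multiplex set: the ordered reporter
channels, their expected reporter-ion m/z, the isotopic impurity matrix of
the label lot, which channels carry no peptide at all (label-only or unused),
which channels carry only background signal (interference-only, i.e. free of
the spiked proteome in a two-proteome design), and the group design.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import ConfigurationError


class Group(NamedTuple):
    """One design group: its channels and the spiked-proteome amount."""

    channels: tuple[str, ...]
    spike_amount: float


def builtin_reporter_mz(plex: str) -> dict[str, float]:
    """Reporter-ion m/z table for a built-in label chemistry.

    Supported keys: ``tmt10``, ``tmt11``, ``tmtpro16``, ``tmtpro18``.
    """
    text = resources.files("tmtd.data").joinpath("reporter_ions.json").read_text()
    tables = json.loads(text)
    if plex not in tables:
        raise ConfigurationError(
            f"unknown label chemistry {plex!r}; available: {sorted(tables)}"
        )
    return dict(tables[plex])


@dataclass(frozen=True)
class ChannelLayout:
    """Channel names, reporter masses, impurities and group design.

    ``impurity_matrix`` follows the product-sheet convention: columns index
    the labeled channel, rows the channel in which signal is detected, so
    ``observed = M @ true``.
    """

    channel_names: tuple[str, ...]
    reporter_mz: Mapping[str, float]
    impurity_matrix: np.ndarray | None = None
    empty_channels: frozenset[str] = frozenset()
    interference_only_channels: frozenset[str] = frozenset()
    groups: Mapping[str, Group] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate channel names")
        missing = [c for c in names if c not in self.reporter_mz]
        if missing:
            raise ConfigurationError(f"channels without reporter m/z: {missing}")
        unknown = (set(self.empty_channels) | set(self.interference_only_channels)) - set(names)
        if unknown:
            raise ConfigurationError(f"unknown channels referenced: {sorted(unknown)}")
        if self.empty_channels & self.interference_only_channels:
            raise ConfigurationError(
                "interference-only channels must carry peptide and cannot be empty"
            )
        if self.impurity_matrix is not None:
            m = np.asarray(self.impurity_matrix, dtype=float)
            if m.shape != (len(names), len(names)):
                raise ConfigurationError(
                    f"impurity matrix shape {m.shape} does not match {len(names)} channels"
                )
            colsums = m.sum(axis=0)
            if np.any(colsums > 1 + 1e-9):
                raise ConfigurationError("impurity matrix column sums exceed 1")
            object.__setattr__(self, "impurity_matrix", m)
        seen: list[str] = []
        for g in self.groups.values():
            for c in g.channels:
                if c not in names:
                    raise ConfigurationError(f"group references unknown channel {c!r}")
                if c in self.empty_channels:
                    raise ConfigurationError(f"group channel {c!r} is declared empty")
                seen.append(c)
        if len(seen) != len(set(seen)):
            raise ConfigurationError("a channel appears in more than one group")

    # ------------------------------------------------------------------ sets
    @property
    def peptide_channels(self) -> tuple[str, ...]:
        """All non-empty channels, in layout order (Eq-10-style set C)."""
        return tuple(c for c in self.channel_names if c not in self.empty_channels)

    @property
    def quant_channels(self) -> tuple[str, ...]:
        """Peptide channels that can carry spiked-proteome signal.

        This is the denominator set of the observed interference level:
        peptide channels minus the interference-only ones.
        """
        return tuple(
            c for c in self.peptide_channels if c not in self.interference_only_channels
        )

    def group_of(self, channel: str) -> str | None:
        for label, g in self.groups.items():
            if channel in g.channels:
                return label
        return None

    # --------------------------------------------------------------- design
    def design_fold_changes(self) -> dict[tuple[str, str], float]:
        """Pairwise theoretical spiked-proteome fold changes between groups.

        Only pairs where both groups have a positive spike amount have a
        finite fold change; pairs against a zero-amount group are omitted.
        """
        out: dict[tuple[str, str], float] = {}
        items = list(self.groups.items())
        for i, (la, ga) in enumerate(items):
            for lb, gb in items[i + 1 :]:
                if ga.spike_amount > 0 and gb.spike_amount > 0:
                    hi, lo = ((la, ga), (lb, gb))
                    if ga.spike_amount < gb.spike_amount:
                        hi, lo = lo, hi
                    out[(hi[0], lo[0])] = hi[1].spike_amount / lo[1].spike_amount
        return out

    # ------------------------------------------------------------------- io
    @classmethod
    def from_dict(cls, d: dict, impurity_matrix: np.ndarray | None = None) -> "ChannelLayout":
        names = tuple(d["channel_names"])
        reporter = d.get("reporter_mz")
        if reporter is None:
            reporter = builtin_reporter_mz(d["plex"])
        groups = {
            label: Group(tuple(g["channels"]), float(g["spike_amount"]))
            for label, g in d.get("groups", {}).items()
        }
        m = impurity_matrix
        if m is None and "impurity_matrix" in d:
            m = np.asarray(d["impurity_matrix"], dtype=float)
        return cls(
            channel_names=names,
            reporter_mz={c: float(reporter[c]) for c in names},
            impurity_matrix=m,
            empty_channels=frozenset(d.get("empty_channels", ())),
            interference_only_channels=frozenset(d.get("interference_only_channels", ())),
            groups=groups,
        )

    @classmethod
    def from_file(cls, path, impurity_csv=None) -> "ChannelLayout":
        """Read a layout from a TOML or JSON config file.

        ``impurity_csv`` optionally points at a headerless CSV holding the
        square impurity matrix in layout channel order.
        """
        path = str(path)
        with open(path, "rb") as fh:
            if path.endswith(".json"):
                d = json.load(fh)
            else:
                d = tomllib.load(fh)
        m = None
        if impurity_csv is not None:
            m = np.loadtxt(impurity_csv, delimiter=",", dtype=float)
        return cls.from_dict(d, impurity_matrix=m)

    def to_dict(self) -> dict:
        d: dict = {
            "channel_names": list(self.channel_names),
            "reporter_mz": {c: self.reporter_mz[c] for c in self.channel_names},
            "empty_channels": sorted(self.empty_channels),
            "interference_only_channels": sorted(self.interference_only_channels),
            "groups": {
                label: {"channels": list(g.channels), "spike_amount": g.spike_amount}
                for label, g in self.groups.items()
            },
        }
        if self.impurity_matrix is not None:
            d["impurity_matrix"] = np.asarray(self.impurity_matrix).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def two_proteome_layout(impurity_matrix: np.ndarray | None = None) -> ChannelLayout:
    """The TMTpro 16plex two-proteome benchmark layout.

    A constant-abundance background proteome in every peptide channel, a
    spiked proteome at relative amounts 0 : 18 : 27 : 36 across four
    three-channel groups (theoretical fold changes 27/18 = 1.5,
    36/27 = 4/3, 36/18 = 2), channel 126C labeled without peptide, three
    channels (128N/129N/130N) free of the spiked proteome, and three
    channels unused.
    """
    reporter = builtin_reporter_mz("tmtpro16")
    names = tuple(reporter)
    return ChannelLayout(
        channel_names=names,
        reporter_mz=reporter,
        impurity_matrix=impurity_matrix,
        empty_channels=frozenset({"126C", "127N", "127C", "131N"}),
        interference_only_channels=frozenset({"128N", "129N", "130N"}),
        groups={
            "100:0": Group(("128N", "129N", "130N"), 0.0),
            "100:6": Group(("128C", "129C", "130C"), 18.0),
            "100:9": Group(("131C", "132C", "133C"), 27.0),
            "100:12": Group(("132N", "133N", "134N"), 36.0),
        },
    )
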