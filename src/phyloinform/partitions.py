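"""Partition (charset) schemes over alignment columns.

The text format follows the RAxML charset convention: one definition per
line, 1-based inclusive ranges, with ``\\3`` stride notation for codon
positions, e.g.::

    CAD_pos1 = 1-2008\\3
    CAD_pos2 = 2-2008\\3
    16S = 4854-5300

Multiple comma-separated ranges are allowed. A column may belong to at
most one partition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["PartitionScheme", "PartitionError", "resolve_partitions"]


class PartitionError(ValueError):
    """Raised for malformed or inconsistent partition definitions."""


_RANGE_RE = re.compile(r"^(\d+)(?:-(\d+))?(?:\\(\d+))?$")


@dataclass
class PartitionScheme:
    """Ordered mapping partition name -> sorted 1-based column indices."""

    parts: dict  # name -> np.ndarray of 1-based indices
    width: int

    def __post_init__(self):
        seen = np.zeros(self.width + 1, dtype=np.int64)  # 0 unused
        owner = {}
        for name, idx in self.parts.items():
            idx = np.asarray(sorted(set(int(i) for i in idx)), dtype=np.int64)
            if idx.size and (idx[0] < 1 or idx[-1] > self.width):
                raise PartitionError(
                    f"partition {name!r} has indices outside 1-{self.width}"
                )
            if idx.size:
                clash = idx[seen[idx] > 0]
                if clash.size:
                    i = int(clash[0])
                    raise PartitionError(
                        f"column {i} assigned to both {owner[i]!r} and {name!r}"
                    )
                seen[idx] = 1
                for i in idx:
                    owner[int(i)] = name
            self.parts[name] = idx

    @property
    def names(self) -> list:
        return list(self.parts)

    def length(self, name: str) -> int:
        """Number of columns in the partition (the L used for averaging)."""
        return int(self.parts[name].size)

    @property
    def lengths(self) -> dict:
        return {name: int(idx.size) for name, idx in self.parts.items()}

    def columns0(self, name: str) -> np.ndarray:
        """0-based column indices for a partition."""
        return self.parts[name] - 1

    def items0(self):
        for name in self.parts:
            yield name, self.columns0(name)

    def to_text(self) -> str:
        lines = []
        for name, idx in self.parts.items():
            lines.append(f"{name} = {_compact_ranges(idx)}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path, width: int) -> "PartitionScheme":
        with open(path) as fh:
            return resolve_partitions(fh.read(), width)


def _compact_ranges(idx: np.ndarray) -> str:
    """Render an index set as comma-separated runs (constant-stride aware)."""
    if idx.size == 0:
        return ""
    idx = np.asarray(idx)
    runs = []
    start = prev = int(idx[0])
    step = None
    for i in idx[1:]:
        i = int(i)
        if step is None or i - prev == step:
            step = i - prev
            prev = i
            continue
        runs.append((start, prev, step))
        start = prev = i
        step = None
    runs.append((start, prev, step if step is not None else 1))
    out = []
    for a, b, s in runs:
        if a == b:
            out.append(str(a))
        elif s == 1:
            out.append(f"{a}-{b}")
        else:
            out.append(f"{a}-{b}\\{s}")
    return ", ".join(out)


def resolve_partitions(text: str, width: int) -> PartitionScheme:
    """Parse charset definitions into explicit column sets.

    Lines of the form ``NAME = start-end[\\stride][, more ranges]``;
    a leading ``DNA,`` data-type tag is tolerated. 1-based inclusive.
    """
    parts: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("dna,"):
            line = line[4:].strip()
        if "=" not in line:
            raise PartitionError(f"line {lineno}: expected 'NAME = ranges'")
        name, _, spec = line.partition("=")
        name = name.strip()
        if not name:
            raise PartitionError(f"line {lineno}: empty partition name")
        if name in parts:
            raise PartitionError(f"line {lineno}: duplicate partition {name!r}")
        cols: list = []
        for token in spec.split(","):
            token = token.strip().replace(" ", "")
            m = _RANGE_RE.match(token)
            if not m:
                raise PartitionError(
                    f"line {lineno}: bad range {token!r} in {name!r}"
                )
            a = int(m.group(1))
            b = int(m.group(2)) if m.group(2) else a
            stride = int(m.group(3)) if m.group(3) else 1
            if a > b or stride < 1:
                raise PartitionError(
                    f"line {lineno}: bad range {token!r} in {name!r}"
                )
            if a < 1 or b > width:
                raise PartitionError(
                    f"line {lineno}: range {token!r} outside 1-{width}"
                )
            cols.extend(range(a, b + 1, stride))
        parts[name] = np.asarray(cols, dtype=np.int64)
    return PartitionScheme(parts, width)
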