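"""Named compounds of the chemoenzymatic HS/heparin library.

Structures stated verbatim in the running text are flagged ``printed``;
the remainder are flagged ``reconstructed`` because only the synthesis
route, not the final string, pins them down (see docs/methods.md for the
reconstruction logic and its assumptions).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .glycans import Oligosaccharide, parse_sequence


@dataclass(frozen=True)
class Fixture:
    name: str
    oligo: Oligosaccharide
    flag: str  # "printed" | "reconstructed"
    sequence: str


@lru_cache(maxsize=1)
def _load() -> dict[str, Fixture]:
    text = (resources.files("heparlib") / "data" / "fixtures.tsv").read_text()
    out: dict[str, Fixture] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, seq, flag = line.split("\t")
        out[name] = Fixture(name, parse_sequence(seq), flag, seq)
    return out


def fixture_names() -> list[str]:
    return list(_load())


def get_fixture(name: str) -> Fixture:
    """Look up a named compound (seed, I..VII, 14, 28, 46, 65, 66)."""
    try:
        return _load()[name]
    except KeyError:
        raise KeyError(
            f"unknown compound {name!r}; known: {', '.join(_load())}") from None
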