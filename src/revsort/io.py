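"""Gene-order file I/O and result rendering.

The file dialect is deliberately minimal: gene tokens separated by any
whitespace (including newlines), lines starting with ``#`` ignored.  Integer
tokens are parsed as integers, anything else is kept as a string label.
Gene orders are not sequences, so no sequence container format applies.
"""

from __future__ import annotations

import sys
from importlib import resources
from pathlib import Path
from typing import IO, Optional, Union

from .core import GeneOrder, ValidationError, interior, validate_gene_order
from .greedy import SortingResult

OUTPUT_MODES = ("distance", "intervals", "process")


class UsageError(ValueError):
    """Caller asked for an output that the result cannot provide."""


def parse_gene_tokens(text: str) -> GeneOrder:
    tokens = []
    for line in text.splitlines():
        if line.lstrip().startswith("#"):
            continue
        tokens.extend(line.split())
    parsed = tuple(int(t) if t.lstrip("-").isdigit() else t for t in tokens)
    report = validate_gene_order(parsed)
    if not report.ok:
        raise ValidationError(report.message)
    return parsed


def read_gene_order(path: Union[str, Path]) -> GeneOrder:
    """Read and validate a whitespace-separated gene-order file."""
    return parse_gene_tokens(Path(path).read_text(encoding="utf-8"))


def write_gene_order(order: GeneOrder, path: Union[str, Path]) -> None:
    Path(path).write_text(" ".join(str(t) for t in order) + "\n", encoding="utf-8")


def packaged_fixture(name: str) -> GeneOrder:
    """Load a gene order shipped with the package (``mouse_193``/``human_193``)."""
    text = resources.files("revsort.data").joinpath(f"{name}.txt").read_text("utf-8")
    return parse_gene_tokens(text)


def format_result(result: SortingResult, mode: str) -> str:
    if mode not in OUTPUT_MODES:
        raise UsageError(f"unknown output mode {mode!r}")
    if mode == "distance":
        return f"distance {result.distance}\n"
    if mode == "intervals":
        return "".join(
            f"{step} {r.i} {r.j}\n" for step, r in enumerate(result.reversals, 1)
        )
    if result.trace is None:
        raise UsageError("process output requires a sorting run with keep_trace=True")
    lines = []
    for step, (r, e) in enumerate(zip(result.reversals, result.trace), 1):
        perm = " ".join(str(v) for v in interior(e))
        lines.append(f"{step} {r.i} {r.j} {perm}\n")
    return "".join(lines)


def write_result(
    result: SortingResult,
    mode: str,
    path: Optional[Union[str, Path, IO[str]]] = None,
) -> None:
    """Render a sorting result in one of the three output modes.

    ``distance``: one line ``distance <d>``.  ``intervals``: one line per
    reversal, ``<step> <i> <j>`` (1-based inclusive).  ``process``: per
    reversal the interval followed by the full permutation after applying
    it (requires a retained trace).  Writes UTF-8 to ``path`` or stdout.
    """
    text = format_result(result, mode)
    if path is None:
        sys.stdout.write(text)
    elif hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")
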