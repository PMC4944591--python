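"""Reading and writing contact-count data.

Two text dialects are accepted, because survey extracts come both ways:

* raw degrees — one positive integer per line, one line per respondent;
* counts CSV — header ``degree,count`` then one row per distinct degree.

Auto-detection sniffs the first non-blank line; an explicit ``dialect``
argument overrides it.  Zero degrees are rejected with a pointer at the
zero-censoring convention (respondents reporting no contacts are not part
of the data the model is fit to).
"""

from __future__ import annotations

from pathlib import Path

from .model_core import DegreeCounts

__all__ = ["read_counts", "write_counts"]

_HEADER = "degree,count"


def _err(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def _parse_degree(tok: str, path, lineno: int) -> int:
    try:
        k = int(tok)
    except ValueError:
        raise _err(path, lineno, f"not an integer degree: {tok!r}") from None
    if k < 0:
        raise _err(path, lineno, f"negative degree {k}")
    if k == 0:
        raise _err(
            path,
            lineno,
            "degree 0 found: zero contact reports are censored in this model "
            "(the likelihood is zero-truncated); drop them from the input",
        )
    return k


def read_counts(path, dialect: str | None = None) -> DegreeCounts:
    """Load a :class:`DegreeCounts` from a raw-degree or degree-count file.

    ``dialect`` may be ``"raw"``, ``"csv"`` or ``None`` (sniff the header).
    Malformed lines are reported with their line numbers.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    stripped = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not stripped:
        raise ValueError(f"{path}: empty input")
    if dialect is None:
        dialect = "csv" if "," in stripped[0][1] else "raw"
    if dialect not in ("raw", "csv"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'raw' or 'csv')")
    counts: dict[int, int] = {}
    if dialect == "csv":
        first_no, first = stripped[0]
        body = stripped
        if first.lower().replace(" ", "") == _HEADER:
            body = stripped[1:]
        for lineno, ln in body:
            parts = [p.strip() for p in ln.split(",")]
            if len(parts) != 2:
                raise _err(path, lineno, f"expected 'degree,count', got {ln!r}")
            k = _parse_degree(parts[0], path, lineno)
            try:
                c = int(parts[1])
            except ValueError:
                raise _err(path, lineno, f"not an integer count: {parts[1]!r}") from None
            if c < 0:
                raise _err(path, lineno, f"negative count {c}")
            if k in counts:
                raise _err(path, lineno, f"duplicate degree {k}")
            counts[k] = c
    else:
        for lineno, ln in stripped:
            k = _parse_degree(ln, path, lineno)
            counts[k] = counts.get(k, 0) + 1
    return DegreeCounts(counts=counts)


def write_counts(y: DegreeCounts, path) -> None:
    """Write the canonical degree-count CSV (sorted by degree).

    ``write_counts`` and :func:`read_counts` round-trip byte-identically
    on canonical files.
    """
    path = Path(path)
    lines = [_HEADER] + [f"{k},{y.counts[k]}" for k in sorted(y.counts)]
    path.write_text("\n".join(lines) + "\n")
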