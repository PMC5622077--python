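"""Small text-format helpers shared across modules (GMT gene-set files)."""

from __future__ import annotations

from pathlib import Path


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
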