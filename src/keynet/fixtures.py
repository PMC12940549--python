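"""Packaged reference data: the published key-protein table.

The TSV shipped under ``keynet/data`` transcribes the study's key-protein
table for the NH/AS/Tin conditions verbatim (hubs with degrees, partners
with combined scores, per-network 90th-percentile thresholds). Loading it
gives three :class:`~keynet.selection.KeyProteinSet` objects suitable for
the overlap stage without any network download.
"""

from __future__ import annotations

from importlib import resources

from .io import normalize_symbol
from .selection import HDPRecord, HSIPRecord, KeyProteinSet, assemble_key_proteins

__all__ = ["load_published_key_proteins"]


def load_published_key_proteins() -> dict[str, KeyProteinSet]:
    """The published NH/AS/Tin key-protein sets, symbol-normalized."""
    text = (
        resources.files("keynet").joinpath("data/key_proteins.tsv").read_text("utf-8")
    )
    per_condition: dict[str, dict] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        cond = row["condition"]
        entry = per_condition.setdefault(
            cond, {"threshold": int(row["cs_threshold"]), "hdps": {}, "hsips": []}
        )
        hub = normalize_symbol(row["hub"])
        entry["hdps"].setdefault(hub, int(row["hub_degree"]))
        partner = row.get("partner", "").strip()
        if partner:
            entry["hsips"].append(
                HSIPRecord(
                    hub=hub,
                    partner=normalize_symbol(partner),
                    combined_score=int(row["combined_score"]),
                )
            )
    out: dict[str, KeyProteinSet] = {}
    for cond, entry in per_condition.items():
        hdps = tuple(
            HDPRecord(symbol=s, degree=d)
            for s, d in sorted(entry["hdps"].items(), key=lambda kv: -kv[1])
        )
        out[cond] = assemble_key_proteins(
            cond, hdps, tuple(entry["hsips"]), entry["threshold"]
        )
    return out
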