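"""Engine configuration with the published defaults.

All tunables of the pipeline live here: the four relevance-fusion
coefficients (K1=0.2, K2=0.5, K3=0.4, K4=0.8), the HTML zone weights, the
PageRank damping factor, the signature-similarity threshold (0.10), the
relational-table identifier-fraction gate (0.5), the promoter upstream
window, the co-expression highlight threshold (r > 0.75), the batch-query
gene limit (1000) and the retrieval cap (top 1000).

The on-disk format is a flat ``key = value`` dialect that round-trips
exactly through :func:`dump_config` / :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .corpus import DEFAULT_ZONE_WEIGHTS


@dataclass
class EngineConfig:
    k1: float = 0.2
    k2: float = 0.5
    k3: float = 0.4
    k4: float = 0.8
    zone_weight_title: float = DEFAULT_ZONE_WEIGHTS["title"]
    zone_weight_heading: float = DEFAULT_ZONE_WEIGHTS["heading"]
    zone_weight_anchor: float = DEFAULT_ZONE_WEIGHTS["anchor"]
    zone_weight_table: float = DEFAULT_ZONE_WEIGHTS["table"]
    zone_weight_body: float = DEFAULT_ZONE_WEIGHTS["body"]
    damping: float = 0.85
    similarity_threshold: float = 0.10
    min_id_fraction: float = 0.5
    upstream_bp: int = 10000
    highlight_r: float = 0.75
    batch_limit: int = 1000
    top_k: int = 1000

    @property
    def zone_weights(self) -> dict[str, float]:
        return {
            "title": self.zone_weight_title,
            "heading": self.zone_weight_heading,
            "anchor": self.zone_weight_anchor,
            "table": self.zone_weight_table,
            "body": self.zone_weight_body,
        }


def dump_config(config: EngineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in fields(EngineConfig):
            fh.write(f"{f.name} = {getattr(config, f.name)!r}\n")


def load_config(path) -> EngineConfig:
    types = {f.name: f.type for f in fields(EngineConfig)}
    kwargs = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            caster = int if types[key] in ("int", int) else float
            kwargs[key] = caster(value.strip())
    return EngineConfig(**kwargs)
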