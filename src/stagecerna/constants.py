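"""Shared vocabulary: tumor-stage labels and RNA classes."""

#: TNM tumor stages compared against the normal group, in progression order.
STAGES: tuple[str, ...] = ("I", "II", "III", "IV")

#: The normal (non-tumor) group label used in sample tables.
NORMAL: str = "normal"

#: RNA classes appearing in a ceRNA network.
RNA_CLASSES: tuple[str, ...] = ("lncRNA", "miRNA", "mRNA")

#: Classes a miRNA may target (edges are miRNA<->lncRNA and miRNA<->mRNA only).
TARGET_CLASSES: tuple[str, ...] = ("lncRNA", "mRNA")
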