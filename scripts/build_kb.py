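"""Regenerate the bundled knowledgebase JSON from the in-code builder.

Run from the repository root:  python scripts/build_kb.py
"""

from pathlib import Path

from oncotier._default_kb import build_default_knowledgebase
from oncotier.knowledgebase import save_knowledgebase

out = Path(__file__).resolve().parents[1] / "src" / "oncotier" / "data" / "knowledgebase.json"
save_knowledgebase(build_default_knowledgebase(), out)
print(f"wrote {out}")
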