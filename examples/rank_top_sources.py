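"""Rank the bundled foods by omega-3 content within each category.

Content is share-of-fat x fat fraction in g omega-3 per g food; the
display value is the half-up two-decimal rounding used for band
classification (low < 0.01, moderate 0.01-0.02, high > 0.02 g/g).
"""

import omega3diet as od
from omega3diet.content import rank_by_content

tables = od.load_all_bundled()
for name, table in tables.items():
    scored = od.score_table(table.records)
    print(f"\n{name} (n={len(scored)}) — top 5 by omega-3 content:")
    for pos, c in enumerate(rank_by_content(scored, 5), start=1):
        print(
            f"  {pos}. {c.name:<32} {c.content_exact:.4f} g/g "
            f"(display {c.content_display:.2f}, band {c.band.value})"
        )
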