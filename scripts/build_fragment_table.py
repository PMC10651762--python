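"""Regenerate the packaged synthetic-accessibility fragment-score table.

The table is derived by the standard frequency-scoring procedure (log10 of
each radius<=2 circular fragment's occurrence count relative to the fragment
at 80% cumulative coverage) applied to the deterministic synthetic drug-like
corpus from focuslib.fixtures.  Run from the repository root:

    python scripts/build_fragment_table.py
"""

from pathlib import Path

from focuslib.fixtures import fragment_corpus
from focuslib.molprops import build_fragment_scores, write_fragment_table

CORPUS_SEED = 0
CORPUS_N = 300

out = Path(__file__).resolve().parents[1] / "src" / "focuslib" / "data" / "sa_fragment_scores.tsv"
corpus = fragment_corpus(seed=CORPUS_SEED, n=CORPUS_N)
scores = build_fragment_scores(corpus, coverage=0.8, min_count=1, clip=4.0)
write_fragment_table(
    scores,
    out,
    provenance=(
        f"synthetic corpus fixtures.fragment_corpus(seed={CORPUS_SEED}, n={CORPUS_N}); "
        "score=log10(count/count@80%cumulative), count>=1, clip 4"
    ),
)
print(f"wrote {len(scores)} fragment scores to {out}")
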