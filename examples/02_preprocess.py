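"""Clean a raw corpus: keyword filter, dedup, validity, tokenization.

Uses the hand-countable 20-record audit fixture so every removal can be
checked by eye: 3 duplicates go first, then URL-only, hashtag-only and
symbol-only records; 12 posts survive and the report reconciles exactly.
"""

from fuzzysent.fixtures import preprocess_audit_fixture
from fuzzysent.preprocess import preprocess_posts

posts, expected = preprocess_audit_fixture()
clean, report = preprocess_posts(posts)

print(f"input records: {report.n_input}")
print(f"after dedup:   {report.n_after_dedup}")
print(f"after validity:{report.n_after_validity}")
print(f"survivors:     {len(clean)}")
print("removals by reason:")
for reason, n in sorted(report.removal_counts.items()):
    print(f"  {reason:14s} {n}")
print(f"conservation holds: {report.conserved()}")
print(f"matches hand counts: {report.removal_counts == expected}")
# Every removed record is attributed to exactly one reason, so
# n_input = survivors + sum(removals) at every stage.
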