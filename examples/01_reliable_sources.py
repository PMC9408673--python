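"""Score web pages for reliability from their link structure.

Builds a small link graph, assembles the column-stochastic transfer matrix
(entry (i, j) = 1/outdegree(j) when page j links to page i), runs the damped
random-surfer iteration, and selects the pages scoring at or above the
uniform baseline 1/N.
"""

from epiwatch import build_transfer_matrix, score_pages, select_reliable
from epiwatch.corpus import WebPage

# page 1 has ten out-links, one of them to page 2; pages 4 and 5 both cite 2
pages = [
    WebPage(1, "https://example.org/1", frozenset(range(2, 12))),
    WebPage(2, "https://example.org/2", frozenset({1})),
    WebPage(3, "https://example.org/3", frozenset({2})),
    WebPage(4, "https://example.org/4", frozenset({2})),
    WebPage(5, "https://example.org/5", frozenset({2})),
] + [WebPage(p, f"https://example.org/{p}", frozenset()) for p in range(6, 12)]

tm = build_transfer_matrix(pages)
print(f"transfer matrix: {tm.size} x {tm.size}")
print(f"entry (row 2, col 1) = {tm.entry(2, 1):.2f}  "
      "(page 1 spreads its vote over its 10 out-links)")

scores = score_pages(tm, damping=0.85)
print(f"\nconverged: {scores.converged} after {scores.iterations} iterations")
for pid in sorted(scores.scores, key=scores.scores.get, reverse=True)[:3]:
    print(f"  page {pid}: reliability {scores.scores[pid]:.4f}")

reliable = select_reliable(scores)
print(f"\nreliable pages (score >= 1/N = {1 / tm.size:.4f}): {sorted(reliable)}")
print("page 2 collects links from three pages, so it tops the ranking;")
print("pages nobody cites fall below the uniform baseline and are dropped.")
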