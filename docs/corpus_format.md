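# Corpus file formats

All inputs are UTF-8 JSON Lines: one JSON object per line.

## Message corpus (`corpus.jsonl`)

Publisher and message records interleaved (publishers conventionally
first). Unknown fields are ignored.

### Publisher record

```json
{"kind": "publisher", "publisher_id": "pub_001", "name_is_real": true,
 "platform_tier": 3, "history_count": 120, "false_history_prob": 0.0}
```

| field | type | notes |
|---|---|---|
| publisher_id | string | unique key, referenced by messages |
| name_is_real | bool | real-name account flag (feature F6) |
| platform_tier | int | 1, 2 or 3: primary / intermediate / advanced (F7) |
| history_count | int ≥ 0 | messages released historically (F8) |
| false_history_prob | float [0,1] | regulatory state (F9); 0 for unseen publishers |

### Message record

```json
{"kind": "message", "message_id": "msg_00001", "publisher_id": "pub_001",
 "timestamp": "2020-02-04",
 "clauses": [{"tokens": [["virus", "noun"], ["spreads", "verb"]],
              "polarity": "negative"}],
 "raw_char_count": 120, "effective_char_count": 96,
 "places": ["wuhan"], "label": "true_info"}
```

| field | type | notes |
|---|---|---|
| message_id | string | unique |
| publisher_id | string | must resolve to a publisher record |
| timestamp | ISO date | calendar day; the warning stage's unit time |
| clauses | list | pre-segmented; each clause has `tokens` (pairs of token and POS tag in noun/verb/adjective/adverb/other) and `polarity` (positive/negative/neutral) |
| raw_char_count | int ≥ 0 | T, total characters |
| effective_char_count | int ≤ raw | E, characters after removing invalid ones |
| places | list of strings | place mentions, mapped to provinces via a gazetteer |
| label | string or null | `true_info` / `false_info` ground truth, optional |

Annotations (segmentation, POS, polarity) are supplied in the file; the
package does not run a tagger. `epiwatch.corpus.annotate_text` is a naive
lexicon-based fallback for raw text.

## Link graph (`link_graph.jsonl`)

```json
{"page_id": 1, "url": "https://example.org/1", "out_links": [2, 5, 9],
 "text": "optional page text"}
```

`page_id` is a unique integer ≥ 1; `out_links` lists page ids this page
links to (self-links and unknown targets are dropped when the transfer
matrix is built).

## Auxiliary files

* **Feature words / sentiment lexicon**: plain text, one term per line.
* **Gazetteer**: two-column CSV `place,province`.
* **Feature matrix export**: CSV with header `f1..f9,label`, indexed by
  message id.
* **Indicator output**: CSV with columns `date,i1,i2,i3,i4,i5`.
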