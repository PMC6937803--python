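"""Independent brute-force oracle for keyword negation used by tests.

Re-derives the decision from scratch: for each keyword token, enumerate
every possible placement of every trigger phrase before it in the same
sentence and check whether one ends inside the pre-match window.
"""

from sclerotype.features import DEFAULT_KEYWORDS, KeywordConfig, _match_positions, _sentences, _tokens


def window_oracle(text: str, config: KeywordConfig = DEFAULT_KEYWORDS) -> bool:
    for sent in _sentences(text):
        toks = _tokens(sent)
        for pos in _match_positions(toks, config.stems):
            negated = False
            for trig in config.triggers:
                words = trig.lower().split()
                for start in range(0, pos):
                    end = start + len(words) - 1
                    if end < pos and list(toks[start : end + 1]) == words:
                        if end >= pos - config.window:
                            negated = True
            if not negated:
                return True
    return False
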