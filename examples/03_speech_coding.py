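"""Condition timelines and private-speech behavioral measures.

The preparation phase is split into private speech (annotated overt
self-directed speech) and inner speech (the remainder); execution is
outer speech. A timed transcript is segmented into utterances at pauses
strictly exceeding 2 s, giving the measures U, W_PS, U/S and W/U.
"""

from fnirspeech.io import EventAnnotation, Token
from fnirspeech.segmentation import (
    build_condition_timeline,
    private_speech_measures,
    segment_utterances,
)

events = EventAnnotation(
    intervals=[
        ("rest", 0.0, 180.0),
        ("preparation", 180.0, 780.0),
        ("execution", 780.0, 1080.0),
        ("private_speech", 200.0, 230.0),
        ("private_speech", 400.0, 460.0),
    ]
)
tl = build_condition_timeline(events, fs=10.0)
for cond in ("rest", "private", "inner", "outer"):
    print(f"{cond:8s} {tl.duration_s(cond):6.1f} s in {len(tl.segments(cond))} segment(s)")

# transcript: three bursts of words; the 2 s pause between the first two
# does NOT split (the rule is a pause *exceeding* two seconds)
tokens = (
    [Token(w, "EN", 200.0 + 0.5 * i) for i, w in enumerate("the tree grows up".split())]
    + [Token(w, "ZH", 203.5 + 0.5 * i) for i, w in enumerate(["等到", "春天"])]
    + [Token(w, "EN", 410.0 + 0.5 * i) for i, w in enumerate("faster than the boy".split())]
)
utts = segment_utterances(tokens, pause_s=2.0)
m = private_speech_measures(utts, cumulative_ps_seconds=tl.duration_s("private"))
print(f"U = {m.n_utterances} utterances, W_PS = {m.n_words} words (EN+ZH), "
      f"U/S = {m.utterances_per_second:.4f}, W/U = {m.words_per_utterance:.2f}")

# U/S divides by the cumulative private-speech duration (90 s here), the
# behavioral rate measure comparable across participants.
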