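"""Parse a CHAT transcript and produce the fixed-length token encoding.

Writes a tiny .cha file with CHAT annotation (a retracing marker, an event
code, a dependent tier), parses the participant tier, and encodes it to a
fixed 32-token sequence.
"""

import tempfile
from pathlib import Path

from demfusion import encode_text, parse_chat

cha = """@UTF8
@Begin
@Languages:\teng
@Participants:\tPAR Participant, INV Investigator
@ID:\teng|demo|S042|||||Participant|||
*INV:\twhat is happening in this picture ?
*PAR:\tthe boy [/] the boy is reaching for the cookie jar .
%mor:\tdet|the n|boy det|the n|boy aux|be v|reach-PROG prep|for det|the n|cookie n|jar .
*PAR:\t<the stool> [//] the stool is falling &=laughs .
@End
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "S042.cha"
    path.write_text(cha)
    transcript = parse_chat(path, speakers=("PAR",))

print(f"subject: {transcript.subject_id}, {len(transcript.utterances)} PAR utterances")
for speaker, text in transcript.utterances:
    print(f"  {speaker}: {text}")

enc = encode_text(transcript, max_len=32)
print(f"encoding length: {len(enc)} (CLS + words + SEP + padding)")
print(f"real tokens: {int(enc.pad_mask.sum())}, pad tokens: {int((~enc.pad_mask).sum())}")
# Retracing markers are stripped but the repeated words stay: disfluencies
# are part of the clinical signal.
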