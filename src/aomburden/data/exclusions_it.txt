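# Free-text diagnosis strings that match the otitis search patterns
# ("oti*", "*oti*", "om*", "*om*") but are not acute otitis media.
# One exact (normalized) string per line; emulates expert review.
vomito
vomito e diarrea
dolore addominale
gomito dolorante
sindrome influenzale
stomatite
addome acuto
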