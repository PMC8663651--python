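# Small built-in demonstration lexicon: token <TAB> channel <TAB> intensity
terrified	fear	0.8
terrified	valence	0.1
scared	fear	0.6
afraid	fear	0.55
fearful	fear	0.65
furious	anger	0.85
furious	valence	0.1
angry	anger	0.7
annoyed	anger	0.45
enraged	anger	0.9
devastated	sadness	0.85
devastated	valence	0.05
sad	sadness	0.6
miserable	sadness	0.7
hopeless	sadness	0.75
crying	sadness	0.65
happy	joy	0.7
happy	valence	0.85
joyful	joy	0.8
joyful	valence	0.9
delighted	joy	0.85
relieved	joy	0.5
relieved	valence	0.7
awful	valence	0.1
awful	sadness	0.5
terrible	valence	0.1
terrible	fear	0.45
great	valence	0.8
good	valence	0.7
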