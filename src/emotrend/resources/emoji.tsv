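# emoji <TAB> replacement word(s); applied before tokenization.
😀	happy
😃	happy
😄	happy
😁	grinning
😆	laughing
😂	laughing
🤣	laughing
🙂	smiling
😊	happy
😉	winking
😍	love
🥰	love
❤	love
❤️	love
💕	love
💖	love
😢	crying
😭	crying
😿	crying
😞	disappointed
😔	sad
☹	sad
☹️	sad
🙁	sad
😠	angry
😡	furious
🤬	furious
😤	angry
😱	terrified
😨	fearful
😰	anxious
😥	worried
😳	shocked
😲	astonished
😮	surprised
🤯	astonished
🎉	celebrate
👍	good
👎	bad
💀	dead
😴	sleepy
🙃	smiling
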