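# Six bundled demonstration prompts (one per line) in a brief conversational
# style. Replace with your own file to replicate a specific study.
Most people start the day by getting up and going to work.
Tell me a little about your family and the people you live with.
Yesterday I went to the market and saw something unusual.
When I was a child, my favorite thing to do was play outside.
The best trip I ever took started early one summer morning.
Lately I have been thinking a lot about my plans for the future.
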