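# The six relationship-section interview questions, verbatim.
Q1: "So, this first section is about family, friendships and relationships. Do you have important relationships in your life? Please describe them."
Q2: "What makes those relationships meaningful to you?"
Q3: "Do you feel that there are people in your life who fully understand you?"
Q4: "How often do you spend time with or connect (via phone, email, or social media) with others?"
Q5: "Do you feel you are part of a larger community? Please explain."
Q6: "When you are feeling disconnected or isolated what do you do?"
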