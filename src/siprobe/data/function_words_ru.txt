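# Russian function words: prepositions and the conjunction "и".
# One token per line; lines starting with '#' are ignored.
# conjunction
и
# prepositions
без
безо
благодаря
в
вблизи
ввиду
вдоль
вместо
вне
внутри
во
возле
вокруг
вопреки
вследствие
для
до
за
из
из-за
из-под
изо
к
ко
кроме
между
мимо
на
над
надо
насчет
насчёт
о
об
обо
около
от
ото
перед
передо
по
под
подо
после
посреди
при
про
против
путем
путём
ради
с
сверх
среди
сквозь
со
согласно
у
через
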